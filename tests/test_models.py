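import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epistasim as ep
from epistasim import FormatError, ModelError, NoSolutionError

from conftest import naive_heritability, naive_prevalence


# ---------------------------------------------------------------------------
# Genotype frequencies and combination genotypes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "maf, expected",
    [
        (0.5, (0.25, 0.50, 0.25)),
        (0.0, (1.0, 0.0, 0.0)),
        (0.2, (0.64, 0.32, 0.04)),
    ],
)
def test_hardy_weinberg_genotype_frequencies(maf, expected):
    triple = ep.genotype_frequencies(maf)
    assert triple.as_array() == pytest.approx(expected, abs=1e-12)
    assert triple.q_AA + triple.q_Aa + triple.q_aa == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("maf", [-0.1, 0.6, 1.0])
def test_maf_domain_enforced(maf):
    with pytest.raises(ModelError):
        ep.genotype_frequencies(maf)


@pytest.mark.parametrize("order", [1, 2, 3])
def test_combo_encoding_is_a_bijection(order):
    from epistasim.models import combo_codes, combo_index, genotype_label, parse_genotype_label

    seen = set()
    for idx in range(3**order):
        codes = combo_codes(idx, order)
        assert combo_index(codes) == idx
        assert parse_genotype_label(genotype_label(codes)) == codes
        seen.add(codes)
    assert len(seen) == 3**order
    # first locus most significant: index 3^(K-1) flips only the first locus
    assert combo_codes(3 ** (order - 1), order) == (1,) + (0,) * (order - 1)


def test_combo_frequency_examples():
    assert ep.combo_frequency((0, 0), (0.5, 0.5)) == pytest.approx(0.0625, abs=1e-15)
    # K=1 reduces to the per-locus genotype frequencies
    for c in range(3):
        assert ep.combo_frequency((c,), (0.3,)) == pytest.approx(
            ep.genotype_frequencies(0.3).as_array()[c], abs=1e-15
        )
    with pytest.raises(ModelError):
        ep.combo_frequency((0, 0, 0), (0.5, 0.5))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    mafs=st.lists(st.floats(0.0, 0.5, allow_nan=False), min_size=1, max_size=4)
)
def test_combo_frequencies_sum_to_one(mafs):
    weights = ep.all_combo_frequencies(mafs)
    assert weights.size == 3 ** len(mafs)
    assert weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert (weights >= 0).all()


# ---------------------------------------------------------------------------
# Table construction and normalization
# ---------------------------------------------------------------------------

def test_threshold_table_matches_reference_two_locus_pattern(table1):
    cells = table1.values.reshape(3, 3)
    # one value wherever either locus is homozygous common, another elsewhere
    for i, j in itertools.product(range(3), repeat=2):
        expected = 0.084 if (i == 0 or j == 0) else 0.210
        assert cells[i, j] == pytest.approx(expected, abs=1e-12)
    assert not table1.normalized


def test_multiplicative_collapses_to_constant_at_unit_relative_risk():
    spec = ep.canonical_spec("multiplicative", 2)
    t = ep.build_table(spec, 0.1, 1.0, [0.3, 0.4])
    assert t.values == pytest.approx(np.full(9, 0.1), abs=1e-15)


def test_zero_baseline_gives_all_zero_table():
    for kind in ep.models.CANONICAL_MODEL_TYPES:
        t = ep.build_table(ep.canonical_spec(kind, 2), 0.0, 3.0, [0.2, 0.2])
        assert (t.values == 0).all()


def test_negative_cell_error_names_the_cell():
    spec = ep.EMEModelSpec(
        order=1,
        labels=("AA", "Aa", "aa"),
        expressions=tuple(
            ep.PenetranceExpression(s) for s in ("x", "x*y", "x-y")
        ),
    )
    with pytest.raises(ModelError, match="aa"):
        ep.build_table(spec, 0.1, 2.0, [0.3])


def test_normalization_applied_when_cells_exceed_one():
    assert ep.normalize_table(np.array([0.5, 1.2])) == pytest.approx(
        [0.5 / 2.2, 1.2 / 2.2], abs=1e-12
    )
    # untriggered below 1; argmax preserved above 1; max mode pins the top cell
    v = np.array([0.2, 0.9, 1.0])
    assert ep.normalize_table(v) is not v and (ep.normalize_table(v) == v).all()
    big = np.array([0.3, 2.0, 1.5])
    assert np.argmax(ep.normalize_table(big)) == 1
    assert ep.normalize_table(big, mode="max").max() == pytest.approx(1.0)
    with pytest.raises(ModelError):
        ep.normalize_table(np.array([-0.1, 2.0]))


def test_build_table_sets_normalized_flag_and_bounds_cells():
    spec = ep.canonical_spec("multiplicative", 2)
    t = ep.build_table(spec, 0.3, 4.0, [0.4, 0.4])  # raw max 0.3*256 = 76.8
    assert t.normalized
    assert (t.values >= 0).all() and (t.values <= 1).all()
    assert t.raw_values.max() == pytest.approx(76.8, rel=1e-12)


# ---------------------------------------------------------------------------
# Prevalence and heritability vs the brute-force oracle
# ---------------------------------------------------------------------------

def test_constant_table_prevalence_and_zero_heritability():
    t = ep.build_table(ep.canonical_spec("multiplicative", 2), 0.1, 1.0, [0.25, 0.45])
    assert ep.prevalence(t) == pytest.approx(0.1, abs=1e-12)
    assert ep.heritability(t) == pytest.approx(0.0, abs=1e-12)


def test_reference_two_locus_prevalence_and_heritability(table1):
    # brute-force oracle values: 0.084*0.4375 + 0.210*0.5625 and Eq.-4 ratio
    assert ep.prevalence(table1) == pytest.approx(0.154875, abs=1e-12)
    assert ep.heritability(table1) == pytest.approx(0.029849661192432177, abs=1e-12)
    assert ep.heritability(table1) == pytest.approx(
        naive_heritability(table1.values, table1.mafs), abs=1e-12
    )


def test_degenerate_mafs_put_all_mass_on_common_cell():
    t = ep.build_table(ep.canonical_spec("threshold", 2), 0.084, 2.5, [0.0, 0.0])
    assert ep.prevalence(t) == pytest.approx(t.values[0], abs=1e-15)


@pytest.mark.parametrize("order", [1, 2, 3, 4])
def test_vectorized_summaries_match_nested_loop_oracle(order):
    rng = np.random.default_rng(100 + order)
    for _ in range(5):
        mafs = rng.uniform(0.05, 0.5, size=order)
        values = rng.uniform(0.0, 1.0, size=3**order)
        t = ep.PenetranceTable(
            order=order, values=values, mafs=mafs, alpha=0.1, f=1.0
        )
        assert ep.prevalence(t) == pytest.approx(
            naive_prevalence(values, mafs), abs=1e-12
        )
        assert ep.heritability(t) == pytest.approx(
            naive_heritability(values, mafs), abs=1e-12
        )


def test_heritability_undefined_at_degenerate_prevalence():
    t = ep.PenetranceTable(order=1, values=np.zeros(3), mafs=np.array([0.3]),
                           alpha=0.0, f=1.0)
    with pytest.raises(ModelError):
        ep.heritability(t)


def test_heritability_bounded_and_vanishing_at_null_relative_risk():
    # each family collapses to a constant table at its null point:
    # f -> 1 for multiplicative/threshold, f -> 0 for additive
    rng = np.random.default_rng(5)
    null_f = {"additive": 1e-7, "multiplicative": 1 + 1e-7, "threshold": 1 + 1e-7}
    for kind in ep.models.CANONICAL_MODEL_TYPES:
        spec = ep.canonical_spec(kind, 2)
        mafs = rng.uniform(0.1, 0.5, size=2)
        near_null = ep.build_table(spec, 0.1, null_f[kind], mafs)
        assert 0.0 <= ep.heritability(near_null) < 1e-10
        some = ep.build_table(spec, 0.1, 2.0, mafs)
        assert 0.0 <= ep.heritability(some) <= 1.0


# ---------------------------------------------------------------------------
# Inverse solving for f
# ---------------------------------------------------------------------------

def test_prevalence_target_equal_to_baseline_recovers_unit_f():
    spec = ep.canonical_spec("multiplicative", 2)
    f = ep.solve_f_given_prevalence(spec, 0.1, 0.1, [0.3, 0.3])
    assert f == pytest.approx(1.0, abs=1e-9)


def test_threshold_inverse_recovers_reference_table(table1):
    spec = ep.canonical_spec("threshold", 2)
    f = ep.solve_f_given_prevalence(spec, 0.084, 0.154875, [0.5, 0.5])
    assert f == pytest.approx(2.5, abs=1e-9)
    t = ep.build_table(spec, 0.084, f, [0.5, 0.5])
    assert t.values == pytest.approx(table1.values, abs=1e-9)


def test_unreachably_low_prevalence_raises():
    spec = ep.canonical_spec("threshold", 2)
    # monotone increasing in f with floor alpha*P(any common) = 0.1*0.4375
    with pytest.raises(NoSolutionError):
        ep.solve_f_given_prevalence(spec, 0.1, 0.01, [0.5, 0.5])


def test_unreachable_heritability_raises():
    # a constant model has h2 identically zero for every f
    flat = ep.EMEModelSpec(
        order=1,
        labels=("AA", "Aa", "aa"),
        expressions=tuple(ep.PenetranceExpression("x") for _ in range(3)),
    )
    with pytest.raises(NoSolutionError):
        ep.solve_f_given_heritability(flat, 0.1, 0.5, [0.3])


def test_heritability_inverse_recovers_reference_f(table1):
    spec = ep.canonical_spec("threshold", 2)
    target = ep.heritability(table1)
    f = ep.solve_f_given_heritability(spec, 0.084, target, [0.5, 0.5])
    assert f == pytest.approx(2.5, abs=1e-8)


def _valid_draw(rng, spec, order):
    """(alpha, f, mafs) whose raw table is already a valid penetrance table."""
    while True:
        alpha = rng.uniform(0.01, 0.3)
        f = rng.uniform(1.1, 5.0)
        mafs = rng.uniform(0.05, 0.5, size=order)
        raw = spec.evaluate(alpha, f)
        if raw.max() <= 1.0:
            return alpha, f, mafs


@pytest.mark.parametrize("kind", ep.models.CANONICAL_MODEL_TYPES)
@pytest.mark.parametrize("order", [2, 3])
def test_solver_round_trips_recover_f(kind, order):
    """Forward prevalence/heritability then inversion recovers f to 1e-8."""
    spec = ep.canonical_spec(kind, order)
    seed = 10 * ep.models.CANONICAL_MODEL_TYPES.index(kind) + order
    rng = np.random.default_rng(seed)
    for _ in range(6):
        alpha, f, mafs = _valid_draw(rng, spec, order)
        t = ep.build_table(spec, alpha, f, mafs)
        f_p = ep.solve_f_given_prevalence(spec, alpha, ep.prevalence(t), mafs)
        assert f_p == pytest.approx(f, abs=1e-8)
        f_h = ep.solve_f_given_heritability(spec, alpha, ep.heritability(t), mafs)
        assert f_h == pytest.approx(f, abs=1e-8)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    alpha=st.floats(0.02, 0.25),
    f=st.floats(1.2, 4.0),
    maf=st.floats(0.1, 0.5),
)
def test_additive_three_locus_heritability_round_trip(alpha, f, maf):
    spec = ep.canonical_spec("additive", 3)
    mafs = np.array([maf, 0.3, 0.4])
    raw = spec.evaluate(alpha, f)
    if raw.max() > 1.0:
        return  # outside the valid-penetrance domain
    target = ep.heritability(ep.build_table(spec, alpha, f, mafs))
    recovered = ep.solve_f_given_heritability(spec, alpha, target, mafs)
    assert recovered == pytest.approx(f, abs=1e-8)


@pytest.mark.parametrize("kind", ep.models.CANONICAL_MODEL_TYPES)
def test_prevalence_monotone_in_relative_risk(kind):
    spec = ep.canonical_spec(kind, 2)
    mafs = [0.2, 0.35]
    grid = np.linspace(0.0, 6.0, 40)
    prevs = [
        float(spec.evaluate(0.05, f) @ ep.all_combo_frequencies(mafs)) for f in grid
    ]
    assert np.all(np.diff(prevs) >= -1e-12)


# ---------------------------------------------------------------------------
# Model files and canonical families
# ---------------------------------------------------------------------------

def test_model_file_round_trip(tmp_path):
    path = tmp_path / "threshold.csv"
    lines = ["genotype,expression"]
    for i in range(9):
        codes = ep.models.combo_codes(i, 2)
        lines.append(
            f"{ep.models.genotype_label(codes)},"
            + ("x" if 0 in codes else "x*y")
        )
    path.write_text("\n".join(lines) + "\n")
    spec = ep.parse_model_file(path)
    assert spec.order == 2
    t = ep.build_table(spec, 0.084, 2.5, [0.5, 0.5])
    expected = ep.build_table(ep.canonical_spec("threshold", 2), 0.084, 2.5, [0.5, 0.5])
    assert t.values == pytest.approx(expected.values, abs=1e-15)


def test_model_file_rows_may_be_shuffled(tmp_path):
    path = tmp_path / "shuffled.csv"
    rows = [
        (ep.models.genotype_label(ep.models.combo_codes(i, 1)), f"x*y^{i}")
        for i in range(3)
    ]
    path.write_text(
        "genotype,expression\n" + "\n".join(f"{g},{e}" for g, e in reversed(rows)) + "\n"
    )
    spec = ep.parse_model_file(path)
    assert [e.text for e in spec.expressions] == ["x*y^0", "x*y^1", "x*y^2"]


@pytest.mark.parametrize(
    "body",
    [
        # 8 rows for an inferred 2-locus model
        "genotype,expression\n"
        + "\n".join(f"{ep.models.genotype_label(ep.models.combo_codes(i, 2))},x"
                    for i in range(8)),
        # duplicate genotype label
        "genotype,expression\nAA,x\nAA,x*y\naa,x",
        # variable other than x, y
        "genotype,expression\nAA,x\nAa,x*z\naa,x",
        # malformed genotype label
        "genotype,expression\nAB,x\nAa,x\naa,x",
    ],
)
def test_model_file_format_errors(tmp_path, body):
    path = tmp_path / "bad.csv"
    path.write_text(body + "\n")
    with pytest.raises(FormatError):
        ep.parse_model_file(path)


def test_additive_single_locus_cells():
    t = ep.build_table(ep.canonical_spec("additive", 1), 0.1, 0.5, [0.3])
    assert t.values == pytest.approx([0.1, 0.15, 0.2], abs=1e-12)


def test_multiplicative_cells_depend_only_on_minor_allele_count():
    spec = ep.canonical_spec("multiplicative", 3)
    t = ep.build_table(spec, 0.05, 1.5, [0.3, 0.3, 0.3])
    s = np.array([sum(ep.models.combo_codes(i, 3)) for i in range(27)])
    for count in range(7):
        cells = t.values[s == count]
        assert np.ptp(cells) <= 1e-15
    # constant ratio f between adjacent total-count levels
    levels = np.array([t.values[s == count][0] for count in range(7)])
    assert levels[1:] / levels[:-1] == pytest.approx(np.full(6, 1.5), abs=1e-12)


def test_unknown_canonical_type_rejected():
    with pytest.raises(ModelError):
        ep.canonical_spec("dominant", 2)


def test_written_model_file_records_achieved_summaries(tmp_path, table1):
    path = tmp_path / "model.csv"
    ep.write_model_file(table1, path, target_mode="prevalence",
                        target_value=0.154875, loci=[3, 7], seed=1)
    text = path.read_text()
    assert "# achieved_prevalence: 0.154875" in text
    assert "# model_loci: 3,7" in text
    assert "genotype,penetrance" in text
    assert text.count("\n") == 9 + text.count("#") + 1
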
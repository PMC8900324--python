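import numpy as np
import pytest

from roseq.errors import ValidationError
from roseq.simulate import (
    SimConfig,
    make_template,
    p_bio_from_ntp_pool,
    run_on_extend,
    run_on_extend_many,
    sample_polymerases,
    simulate_metagene,
    size_select,
)


# ---------------------------------------------------------------- template

def test_template_equal_composition_and_determinism():
    t = make_template(2000, seed=0)
    assert sorted(t.count(b) for b in "ACGT") == [500, 500, 500, 500]
    assert make_template(8, seed=42) == make_template(8, seed=42)
    counts = [make_template(6, seed=1).count(b) for b in "ACGT"]
    assert max(counts) - min(counts) <= 1
    with pytest.raises(ValidationError):
        make_template(3)


# -------------------------------------------------------------- polymerases

def test_polymerase_sampling_counts_and_degenerate_sd():
    cfg = SimConfig(seed=7)
    init, elong = sample_polymerases(cfg)
    assert (len(init), len(elong)) == (10000, 5000)
    assert init.min() >= 0 and init.max() < cfg.template_length
    assert elong.min() >= 300 and elong.max() < 2000
    # law of large numbers on the initiation mean
    assert init.mean() == pytest.approx(50.0, abs=3 * 25 / np.sqrt(10000) + 0.5)
    frozen = SimConfig(init_sd=0.0, seed=1)
    i2, _ = sample_polymerases(frozen)
    assert (i2 == 50).all()
    with pytest.raises(ValidationError):
        SimConfig(elong_range=(100, 3000))


# ----------------------------------------------------------------- run-on

def test_p_bio_one_terminates_at_first_labeled_base():
    rng = np.random.default_rng(0)
    t = make_template(500, rng)
    for pos in range(0, 450, 7):
        end = run_on_extend(pos, t, p_bio=1.0, max_runon=100, rng=rng)
        scan = t.find("C", pos)  # exhaustive oracle
        expected = scan + 1 if 0 <= scan < pos + 100 else min(pos + 100, len(t))
        assert end == expected


def test_p_bio_zero_runs_to_cap_or_template_end():
    t = make_template(200, seed=3)
    assert run_on_extend(0, t, 0.0, max_runon=50) == 50
    assert run_on_extend(180, t, 0.0, max_runon=50) == 200


def test_vectorized_run_on_agrees_with_oracle_at_extremes():
    rng = np.random.default_rng(1)
    t = make_template(2000, rng)
    pos = rng.integers(0, 1900, size=500)
    ends1 = run_on_extend_many(pos, t, 1.0, max_runon=100, rng=rng)
    labeled = np.array([i for i, b in enumerate(t) if b == "C"])
    for p, e in zip(pos, ends1):
        nxt = labeled[labeled >= p]
        expected = nxt[0] + 1 if len(nxt) and nxt[0] < p + 100 else min(p + 100, 2000)
        assert e == expected
    ends0 = run_on_extend_many(pos, t, 0.0, max_runon=100)
    assert np.array_equal(ends0, np.minimum(pos + 100, 2000))


def test_runon_length_is_geometric_with_mean_4_over_p():
    """Equal composition + per-labeled-base halt p => per-base halt p/4,
    so uncapped run-on length averages 4/p (within 5% at p = 0.5)."""
    rng = np.random.default_rng(2)
    means = []
    for _ in range(5):
        t = make_template(200_000, rng)
        pos = rng.integers(0, 100_000, size=20_000)
        ends = run_on_extend_many(pos, t, 0.5, max_runon=100_000, rng=rng)
        means.append((ends - pos).mean())
    assert np.mean(means) == pytest.approx(8.0, rel=0.05)


def test_no_labeled_base_downstream_hits_the_cap():
    t = "A" * 50 + "C" + "A" * 149
    assert run_on_extend(60, t, 1.0, max_runon=100) == 160
    ends = run_on_extend_many(np.array([60]), t, 1.0, max_runon=100,
                              rng=np.random.default_rng(0))
    assert ends[0] == 160


def test_ntp_pool_ratio_mapping():
    assert p_bio_from_ntp_pool(25, 0) == 1.0
    assert p_bio_from_ntp_pool(25, 250) == pytest.approx(25 / 275)
    with pytest.raises(ValidationError):
        p_bio_from_ntp_pool(0, 0)


# ------------------------------------------------------------ size selection

def test_size_selection_closed_form():
    keep, cuts = size_select(np.full(100_000, 25.0), 25.0, seed=11)
    assert cuts.mean() == pytest.approx(25.0, rel=0.02)
    assert keep.mean() == pytest.approx(1 - np.exp(-1), rel=0.02)
    zero, _ = size_select(np.zeros(1000), 25.0, seed=1)
    assert not zero.any()
    huge, _ = size_select(np.full(1000, 1e9), 25.0, seed=1)
    assert huge.all()


def test_retention_monotone_in_length():
    lengths = np.repeat([5.0, 15.0, 25.0, 50.0, 100.0], 20_000)
    keep, _ = size_select(lengths, 25.0, seed=5)
    rates = [keep[lengths == L].mean() for L in (5, 15, 25, 50, 100)]
    assert all(a < b for a, b in zip(rates, rates[1:]))
    expected = [1 - np.exp(-L / 25) for L in (5, 15, 25, 50, 100)]
    assert np.allclose(rates, expected, atol=0.01)


# ------------------------------------------------------------- full passes

def test_simulation_is_deterministic_per_seed():
    a = simulate_metagene(SimConfig(p_bio=0.3), seed=9)
    b = simulate_metagene(SimConfig(p_bio=0.3), seed=9)
    assert a.template == b.template
    assert np.array_equal(a.coverage, b.coverage)
    assert a.short_read_tss_fraction == b.short_read_tss_fraction
    c = simulate_metagene(SimConfig(p_bio=0.3), seed=10)
    assert not np.array_equal(a.coverage, c.coverage)


def test_pro_mode_reads_shorter_than_gro_mode():
    """Biotin termination (p_bio = 0.5) must shorten retained reads
    relative to the unterminated GRO-mode run-on, seed-paired."""
    diffs = []
    for seed in range(10):
        gro = simulate_metagene(SimConfig(p_bio=0.0), seed=seed)
        pro = simulate_metagene(SimConfig(p_bio=0.5), seed=seed)
        diffs.append(gro.mean_retained_length - pro.mean_retained_length)
    diffs = np.array(diffs)
    # paired one-sided check: mean difference clearly positive
    assert diffs.mean() - 1.96 * diffs.std(ddof=1) / np.sqrt(len(diffs)) > 0
    assert (diffs > 0).all()


def test_three_prime_peak_moves_downstream_as_p_bio_drops():
    peaks = {}
    for p in (1.0, 0.1, 0.0):
        r = simulate_metagene(SimConfig(p_bio=p), seed=13)
        smooth = np.convolve(r.three_prime_density, np.ones(5) / 5, mode="same")
        peaks[p] = int(np.argmax(smooth))
    assert peaks[1.0] < peaks[0.1] < peaks[0.0]


def test_short_read_tss_fraction_has_interior_maximum():
    grid = [0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0]
    wins = 0
    for seed in range(10):
        fr = [
            simulate_metagene(SimConfig(p_bio=p), seed=seed).short_read_tss_fraction
            for p in grid
        ]
        wins += max(fr[1:-1]) > max(fr[0], fr[-1])
    assert wins >= 8
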
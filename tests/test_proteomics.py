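"""Total-protein-approach quantification and downstream proteome analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecflux.proteomics import (
    MSRecord,
    allocate_go,
    benjamini_hochberg,
    differential_expression,
    to_molar,
    tpa_quantify,
    translation_rate,
)
from ecflux.synthetic import ToySpec, make_toy_network, simulate_condition, simulate_proteomics


def _records(conc, replicate=1, condition="c1", heavy=1e6):
    """MS records whose light channel is proportional to `conc`."""
    return [
        MSRecord(pid, ibaq_heavy=heavy, ratio_hl=heavy / (c * 100.0),
                 mw=50.0, replicate=replicate, condition=condition)
        for pid, c in conc.items()
    ]


def test_equal_intensities_split_the_megagram():
    sample = tpa_quantify(_records({"p1": 3.0, "p2": 3.0}))
    assert sample.conc["p1"] == pytest.approx(5.0e5)
    assert sample.conc["p2"] == pytest.approx(5.0e5)


def test_concentrations_sum_to_1e6_per_replicate():
    recs = _records({"p1": 1.0, "p2": 5.0, "p3": 0.3}) + _records(
        {"p1": 1.2, "p2": 4.5, "p3": 0.2}, replicate=2
    )
    sample = tpa_quantify(recs)
    for col in sample.replicates.columns:
        assert sample.replicates[col].sum() == pytest.approx(1e6, rel=1e-9)
    assert sample.conc.sum() == pytest.approx(1e6, rel=1e-3)


@pytest.mark.parametrize("recovery", [0.5, 0.8, 1.0])
def test_recovery_factor_cancels_in_shares(recovery):
    base = tpa_quantify(_records({"p1": 1.0, "p2": 4.0}), recovery=0.8)
    other = tpa_quantify(_records({"p1": 1.0, "p2": 4.0}), recovery=recovery)
    pd.testing.assert_series_equal(base.conc, other.conc)


@settings(max_examples=25, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e3))
def test_global_intensity_rescaling_is_invisible(scale):
    a = tpa_quantify(_records({"p1": 1.0, "p2": 4.0}))
    b = tpa_quantify(_records({"p1": scale, "p2": 4.0 * scale}))
    assert np.allclose(a.conc.values, b.conc.values, rtol=1e-9)


def test_invalid_ratio_records_are_excluded():
    recs = _records({"p1": 1.0, "p2": 4.0})
    recs.append(MSRecord("p3", ibaq_heavy=1e6, ratio_hl=0.0, mw=10.0,
                         condition="c1"))
    sample = tpa_quantify(recs)
    assert "p3" not in sample.conc.index


def test_zero_noise_generator_round_trip(glucose_truth, glucose_proteome):
    _, truth = glucose_truth
    conc = glucose_proteome.conc.reindex(truth.conc_ug_per_g.index)
    rel = np.abs(conc - truth.conc_ug_per_g) / truth.conc_ug_per_g
    assert float(rel.max()) <= 1e-9


def test_noisy_recovery_within_three_cv():
    spec = ToySpec(variant="glucose", seed=23, proteomics_cv=0.10, rate_cv=0.0)
    model = make_toy_network(spec)
    _, truth = simulate_condition(model, spec)
    sample = tpa_quantify(simulate_proteomics(truth, spec))
    rel = np.abs(
        sample.conc.reindex(truth.conc_ug_per_g.index) - truth.conc_ug_per_g
    ) / truth.conc_ug_per_g
    # duplicate averaging: SE = CV/sqrt(2); allow 3 CV for 99% of proteins
    assert (rel <= 3 * spec.proteomics_cv).mean() >= 0.99


# -- molar conversion ------------------------------------------------------

def test_molar_conversion_unit_arithmetic():
    sample = tpa_quantify(_records({"p1": 1.0, "p2": 9.0}))
    # p1 holds 1e5 ug/g; with Ptot 0.5 g/gDCW and MW 50 g/mmol -> 1e-3 mmol/gDCW
    out = to_molar(sample, mw={"p1": 50.0, "p2": 50.0}, ptot=0.5)
    assert out["p1"] == pytest.approx(1e-3)


def test_zero_ptot_gives_zero_abundance():
    sample = tpa_quantify(_records({"p1": 1.0}))
    assert to_molar(sample, mw={"p1": 50.0}, ptot=0.0)["p1"] == 0.0


def test_missing_mw_raises():
    sample = tpa_quantify(_records({"p1": 1.0}))
    with pytest.raises(KeyError):
        to_molar(sample, mw={}, ptot=0.5)


def test_total_molar_mass_bounded_by_ptot(glucose_truth, glucose_proteome):
    physiology, truth = glucose_truth
    molar = to_molar(glucose_proteome, mw=truth.protein_mw, ptot=physiology.ptot)
    total = sum(molar[p] * truth.protein_mw[p] for p in molar)
    assert total <= physiology.ptot + 1e-9


# -- differential expression ----------------------------------------------

def _two_rep_sample(name, means, noise):
    recs = []
    for rep, eps in enumerate(noise, start=1):
        recs += _records({p: m * (1 + e) for (p, m), e in zip(means.items(), eps)},
                         replicate=rep, condition=name)
    return tpa_quantify(recs)


def test_identical_groups_are_null():
    means = {"p1": 1.0, "p2": 2.0, "p3": 4.0}
    a = _two_rep_sample("a", means, [[0.01, -0.01, 0.0], [-0.01, 0.01, 0.0]])
    b = _two_rep_sample("b", means, [[0.01, -0.01, 0.0], [-0.01, 0.01, 0.0]])
    table = differential_expression(a, b)
    assert np.allclose(table["log2fc"], 0.0, atol=0.05)
    assert not table["significant"].any()


def test_benjamini_hochberg_hand_example():
    adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_planted_fourfold_change_detected():
    rng = np.random.default_rng(3)
    n = 50  # sizeable background keeps the compositional shift small
    means_a = {f"p{i}": 10.0 for i in range(n)}
    means_b = dict(means_a)
    means_b["p0"] = 40.0  # 4-fold up
    noise = lambda: [list(rng.normal(0, 0.002, size=n)) for _ in range(2)]
    a = _two_rep_sample("a", means_a, noise())
    b = _two_rep_sample("b", means_b, noise())
    table = differential_expression(a, b).set_index("protein_id")
    assert table.loc["p0", "log2fc"] == pytest.approx(2.0, abs=0.2)
    assert bool(table.loc["p0", "significant"])


def test_noisy_proteins_filtered_before_testing():
    a = _two_rep_sample("a", {"p1": 1.0, "p2": 1.0}, [[0.0, 3.0], [0.0, -0.9]])
    b = _two_rep_sample("b", {"p1": 2.0, "p2": 1.0}, [[0.0, 3.0], [0.0, -0.9]])
    table = differential_expression(a, b)
    assert "p2" not in set(table["protein_id"])  # replicate SD exceeds mean


def test_single_replicate_rejected():
    a = tpa_quantify(_records({"p1": 1.0}))
    b = _two_rep_sample("b", {"p1": 1.0}, [[0.0], [0.0]])
    with pytest.raises(ValueError, match="replicates"):
        differential_expression(a, b)


# -- GO allocation ---------------------------------------------------------

def test_go_allocation_shares():
    sample = tpa_quantify(_records({"p1": 1.0, "p2": 1.0, "p3": 2.0}))
    out = allocate_go(sample, {"all": ["p1", "p2", "p3"],
                               "half": ["p1", "p2"],
                               "empty": []}).set_index("group")
    assert out.loc["all", "pct_mass"] == pytest.approx(100.0)
    assert out.loc["half", "pct_mass"] == pytest.approx(50.0)
    assert out.loc["empty", "pct_mass"] == 0.0


def test_ribosome_share_matches_generator_truth(glucose_truth, glucose_proteome):
    _, truth = glucose_truth
    out = allocate_go(glucose_proteome, {"ribosome": truth.ribosomal_ids})
    expected = truth.conc_ug_per_g.loc[truth.ribosomal_ids].sum() / 1e6 * 100
    assert out["pct_mass"].iloc[0] == pytest.approx(expected, abs=0.1)


# -- translation rate ------------------------------------------------------

def test_translation_rate_closed_form():
    """mu = 0.1 1/h, Ptot = 0.5 g/gDCW, N_rib = 1.2626e-7 mol/gDCW
    give 1.0 aa/s."""
    sample = tpa_quantify(_records({"r1": 1.0}))
    # the single ribosomal protein holds the whole proteome (1e6 ug/g);
    # choose its MW so the implied molar abundance is the planted N_rib
    sample.mw = pd.Series({"r1": 0.5 / (1.2626e-7 * 1e3)})
    rate = translation_rate(sample, ["r1"], mu=0.1, ptot=0.5)
    assert rate == pytest.approx(1.0, rel=1e-3)


def test_translation_rate_zero_growth():
    sample = tpa_quantify(_records({"r1": 1.0}))
    sample.mw = pd.Series({"r1": 30.0})
    assert translation_rate(sample, ["r1"], mu=0.0, ptot=0.5) == 0.0


def test_no_ribosomal_proteins_detected_raises():
    sample = tpa_quantify(_records({"p1": 1.0}))
    with pytest.raises(ValueError, match="ribosomal"):
        translation_rate(sample, ["r1"], mu=0.1, ptot=0.5)


def test_planted_translation_rate_recovered(glucose_truth, glucose_proteome):
    physiology, truth = glucose_truth
    rate = translation_rate(glucose_proteome, truth.ribosomal_ids,
                            mu=truth.mu, ptot=physiology.ptot)
    assert rate == pytest.approx(truth.translation_rate, rel=1e-6)


def test_translation_rate_linear_in_growth(glucose_truth, glucose_proteome):
    """At a fixed proteome the per-ribosome rate is proportional to mu,
    the linearity expected across growth conditions."""
    physiology, truth = glucose_truth
    r1 = translation_rate(glucose_proteome, truth.ribosomal_ids, mu=0.1,
                          ptot=physiology.ptot)
    r2 = translation_rate(glucose_proteome, truth.ribosomal_ids, mu=0.2,
                          ptot=physiology.ptot)
    assert r2 == pytest.approx(2.0 * r1, rel=1e-9)
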
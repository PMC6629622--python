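"""Synthetic cohort generator: determinism, prevalences, dwell times and
agreement between emitted measurements and the hidden state truth."""

import numpy as np
import pytest
from scipy import stats as sps

from capnoseq.states import APNEA, MISSING, NORMAL, STATE_ALPHABET, sequences_from_frame
from capnoseq.synth import (
    ARCHETYPES,
    SyntheticCohortConfig,
    default_dwell_params,
    simulate_cohort,
    simulate_effect_cohorts,
)


def small_config(**kw):
    base = dict(n_patients=30, duration_median_s=180, seed=42)
    base.update(kw)
    return SyntheticCohortConfig(**base)


def test_same_seed_gives_identical_cohort():
    a = simulate_cohort(small_config())
    b = simulate_cohort(small_config())
    assert a.monitoring.to_csv(index=False) == b.monitoring.to_csv(index=False)
    assert a.covariates.to_csv(index=False) == b.covariates.to_csv(index=False)
    assert (a.true_archetype == b.true_archetype).all()


def test_single_archetype_cohort_all_normal():
    cfg = small_config(
        archetype_prevalences=(1.0, 0.0, 0.0, 0.0),
        dwell_params={
            NORMAL: {
                "dwell_means": {s: 1e9 if s == NORMAL else 1 for s in STATE_ALPHABET},
                "transition": default_dwell_params()[NORMAL]["transition"],
            },
            **{a: default_dwell_params()[a] for a in ARCHETYPES if a != NORMAL},
        },
        artifact_rate=0.0,
    )
    cohort = simulate_cohort(cfg)
    for seq in sequences_from_frame(cohort.monitoring):
        assert (seq.states == NORMAL).all()


def test_archetype_counts_within_binomial_envelope():
    """Empirical archetype counts at n=200 stay inside the exact binomial
    99% envelope of their configured prevalences."""
    cfg = SyntheticCohortConfig(
        n_patients=200, duration_median_s=120, covariate_effects={}, seed=7
    )
    cohort = simulate_cohort(cfg)
    counts = cohort.true_archetype.value_counts()
    for arch, p in zip(ARCHETYPES, cfg.archetype_prevalences):
        lo = sps.binom.ppf(0.005, 200, p)
        hi = sps.binom.ppf(0.995, 200, p)
        assert lo <= counts.get(arch, 0) <= hi, arch


def test_prevalences_converge_with_covariate_links():
    """Even with the weak covariate links active, frequencies at n=2000 are
    within 3 standard errors of the configured prevalences."""
    cfg = SyntheticCohortConfig(n_patients=2000, duration_median_s=70, seed=3)
    cohort = simulate_cohort(cfg)
    freq = cohort.true_archetype.value_counts(normalize=True)
    for arch, p in zip(ARCHETYPES, cfg.archetype_prevalences):
        se = np.sqrt(p * (1 - p) / 2000)
        assert abs(freq.get(arch, 0.0) - p) <= 3 * se, arch


def test_classifier_recovers_hidden_state_without_artifacts():
    cfg = small_config(n_patients=40, artifact_rate=0.0)
    cohort = simulate_cohort(cfg)
    agree = total = 0
    for seq in sequences_from_frame(cohort.monitoring):
        truth = cohort.true_states[seq.patient_id]
        agree += np.sum(seq.states == truth)
        total += len(seq)
    assert agree / total >= 0.999


def test_missing_only_where_artifact_flagged():
    cohort = simulate_cohort(small_config(artifact_rate=0.2))
    seqs = {s.patient_id: s for s in sequences_from_frame(cohort.monitoring)}
    for pid, g in cohort.monitoring.groupby("patient_id"):
        missing = seqs[pid].states == MISSING
        assert (missing == g["artifact"].to_numpy()).all()


def test_dwell_means_match_configuration():
    """Observed mean run lengths of the dominant state match the configured
    geometric dwell mean within 10% at n=500 patients."""
    # durations long relative to the 90 s dominant dwell, so excluding the
    # boundary-censored first/last runs leaves little length bias
    cfg = SyntheticCohortConfig(
        n_patients=500, duration_median_s=2500, duration_sigma=0.3,
        covariate_effects={}, artifact_rate=0.0, seed=9,
    )
    cohort = simulate_cohort(cfg)
    runs = {a: [] for a in ARCHETYPES}
    for pid, truth in cohort.true_states.items():
        arch = cohort.true_archetype[pid]
        # interior runs only: truncation at the ends biases lengths down
        change = np.flatnonzero(truth[1:] != truth[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(truth)]])
        for a, b in zip(starts[1:-1], ends[1:-1]):
            if truth[a] == arch:
                runs[arch].append(b - a)
    for arch in ARCHETYPES:
        observed = np.mean(runs[arch])
        expected = cfg.dwell_params[arch]["dwell_means"][arch]
        assert observed == pytest.approx(expected, rel=0.10), arch


def test_every_patient_has_at_least_60_seconds():
    cfg = small_config(duration_median_s=65, duration_sigma=0.8)
    cohort = simulate_cohort(cfg)
    lengths = cohort.monitoring.groupby("patient_id").size()
    assert (lengths >= 60).all()


def test_interventions_concentrate_in_apnea_heavy_patients():
    cfg = SyntheticCohortConfig(n_patients=300, duration_median_s=150, seed=5)
    cohort = simulate_cohort(cfg)
    apnea_frac = {
        pid: float(np.mean(s == APNEA)) for pid, s in cohort.true_states.items()
    }
    cov = cohort.covariates.set_index("patient_id")
    got = cov.index[cov["intervention_received"] == 1]
    not_got = cov.index[cov["intervention_received"] == 0]
    assert len(got) > 0
    assert np.mean([apnea_frac[p] for p in got]) > np.mean(
        [apnea_frac[p] for p in not_got]
    )


def test_hyperoxia_predominant_and_desaturation_rare():
    cfg = SyntheticCohortConfig(n_patients=200, duration_median_s=150, seed=13)
    cohort = simulate_cohort(cfg)
    frac_hyper = []
    n_desat = 0
    for _, g in cohort.monitoring.groupby("patient_id"):
        valid = g.loc[g["pulse_detected"], "spo2"]
        frac_hyper.append((valid > 97).mean())
        n_desat += int((valid < 90).any())
    assert np.median(frac_hyper) > 0.8
    assert n_desat / 200 < 0.10  # rare episodes at the configured 3% rate


def test_tcco2_peak_tracks_hypoventilation_burden():
    cfg = SyntheticCohortConfig(n_patients=300, duration_median_s=150, seed=21)
    cohort = simulate_cohort(cfg)
    burden, peak = [], []
    for pid, g in cohort.monitoring.groupby("patient_id"):
        truth = cohort.true_states[pid]
        burden.append(np.mean(truth != "NORMAL"))
        peak.append(g["tcco2"].max())
    assert np.corrcoef(burden, peak)[0, 1] > 0.05


@pytest.mark.parametrize(
    "kw, msg",
    [
        (dict(archetype_prevalences=(0.5, 0.5, 0.5, 0.0)), "sum to 1"),
        (dict(duration_median_s=30.0, duration_sigma=0.1), "below 60"),
        (dict(artifact_rate=1.5), "probabilit"),
        (dict(n_patients=0), "n_patients"),
    ],
)
def test_invalid_configs_rejected(kw, msg):
    with pytest.raises(ValueError, match=msg):
        simulate_cohort(small_config(**kw))


def test_effect_cohorts_scale_target_dwell_with_shared_paths():
    (lo, x), (hi, x2) = simulate_effect_cohorts(40, (1.5, 6.0), seed=2)
    assert set(x) == {0, 1} and (x == x2).all()

    def mean_apnea(cohort, grp):
        cov = cohort.covariates
        pids = cov.loc[cov["x"] == grp, "patient_id"]
        return np.mean(
            [float(np.mean(cohort.true_states[p] == APNEA)) for p in pids]
        )

    # x=0 half shares all randomness, so it is byte-identical across levels
    for pid in lo.covariates.loc[lo.covariates["x"] == 0, "patient_id"]:
        assert (lo.true_states[pid] == hi.true_states[pid]).all()
    assert mean_apnea(hi, 1) > mean_apnea(lo, 1) > mean_apnea(lo, 0)
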
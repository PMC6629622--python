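"""Synthetic sedation-monitoring cohorts with known ground truth.

Emulates per-second capnography monitoring of a procedural-sedation cohort:
each patient belongs to one of four hidden sequence archetypes — dominated
by normal breathing, hypopneic hypoventilation, apnea or bradypneic
hypoventilation, at prevalences 41/37/15/7% by default — and their
respiratory state stream is a semi-Markov chain (geometric dwell times,
archetype-specific mean dwells and transition weights) over those four
states. Per-second respiratory rate, end-tidal CO2 and relative waveform
amplitude are emitted from state-conditional distributions constructed to
sit strictly on the correct side of the classifier cut-offs, so that with
no artifacts the classifier recovers the hidden state exactly. Side
channels follow the clinical picture the analysis assumes: SpO2 is
predominantly hyperoxic (> 97%) with rare desaturation episodes,
transcutaneous CO2 drifts upward with accumulated hypoventilation/apnea
time, and interventions to support breathing are placed preferentially
during apnea. Patient covariates (age, sex, BMI, OSA, STOP-BANG class,
COPD, smoking, ASA, Charlson index, admission type, sedation doses) carry
configurable weak associations with archetype membership via a multinomial
logit on standardized covariates.

Same config and seed give a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import APNEA, BRADYPNEA, HYPOPNEA, NORMAL, STATE_ALPHABET

#: Archetypes are named after their dominant state; prevalence order below.
ARCHETYPES = (NORMAL, HYPOPNEA, APNEA, BRADYPNEA)
DEFAULT_PREVALENCES = (0.41, 0.37, 0.15, 0.07)

#: Margin kept between emitted values and classifier thresholds.
_EPS = 1e-3


def default_dwell_params() -> dict[str, dict]:
    """Per-archetype mean dwell times (s) and next-state transition weights.

    Each archetype spends long spells (mean 90 s) in its dominant state and
    short excursions (mean 10 s) elsewhere, returning to the dominant state
    with weight 0.75; occupancy of the dominant state is then roughly 90%,
    giving well-separated occupancy distributions across archetypes.
    """
    params = {}
    for dom in ARCHETYPES:
        dwell = {s: (90.0 if s == dom else 10.0) for s in STATE_ALPHABET}
        trans = {}
        for s in STATE_ALPHABET:
            others = [t for t in STATE_ALPHABET if t != s]
            if s == dom:
                w = {t: 1.0 / len(others) for t in others}
            else:
                w = {t: (0.75 if t == dom else 0.125) for t in others}
            trans[s] = w
        params[dom] = {"dwell_means": dwell, "transition": trans}
    return params


def default_emission_params() -> dict[str, dict]:
    """State-conditional emission distributions for rate, etCO2, amplitude."""
    return {
        NORMAL: {"rate": (14.0, 2.0), "etco2": (38.0, 3.0), "amp_dev": 0.0},
        HYPOPNEA: {"rate": (13.0, 2.0), "etco2": (33.0, 3.0), "amp_dev": 1.0},
        BRADYPNEA: {"rate": None, "etco2": (42.0, 3.0), "amp_dev": 0.0},
        APNEA: {},
    }


def default_covariate_effects() -> dict[str, tuple[float, float, float, float]]:
    """Per-unit-SD logit shifts of archetype membership, one entry per
    archetype in :data:`ARCHETYPES` order. Small by design: single
    covariates should explain only a few percent of sequence discrepancy."""
    return {
        "osa": (0.0, 0.0, 0.2, 0.6),
        "smoker": (0.0, 0.1, 0.2, 0.8),
        "charlson": (0.0, 0.1, -0.2, 0.5),
        "age": (0.0, 0.1, -0.15, 0.0),
    }


@dataclass
class SyntheticCohortConfig:
    """Generator settings; defaults are the cohort conditions the analysis
    assumes (prevalences 41/37/15/7%, 30-min median procedures, rare
    desaturation, weak covariate-archetype links)."""

    n_patients: int = 102
    archetype_prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    duration_median_s: float = 1800.0
    duration_sigma: float = 0.4
    dwell_params: dict[str, dict] = field(default_factory=default_dwell_params)
    emission_params: dict[str, dict] = field(default_factory=default_emission_params)
    covariate_effects: dict[str, tuple] = field(
        default_factory=default_covariate_effects
    )
    desat_rate: float = 0.03
    artifact_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.archetype_prevalences, dtype=float)
        if p.size != len(ARCHETYPES) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("archetype_prevalences must be 4 probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_prevalences must sum to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        mean_duration = self.duration_median_s * np.exp(self.duration_sigma**2 / 2)
        if mean_duration < 60:
            raise ValueError("duration parameters imply a mean below 60 s")
        for arch, prm in self.dwell_params.items():
            for s, m in prm["dwell_means"].items():
                if m < 1:
                    raise ValueError(f"dwell mean for {arch}/{s} below 1 s")
        for rate in (self.desat_rate, self.artifact_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be probabilities")


@dataclass
class SyntheticCohort:
    """A simulated cohort: long monitoring table, raw covariate table, and
    the hidden archetype / per-second state ground truth."""

    monitoring: pd.DataFrame
    covariates: pd.DataFrame
    true_archetype: pd.Series  # indexed by patient_id
    true_states: dict[str, np.ndarray]
    config: SyntheticCohortConfig

    @property
    def patient_ids(self) -> list[str]:
        return list(self.true_archetype.index)


def _simulate_state_stream(
    rng: np.random.Generator, params: dict, duration: int, dominant: str
) -> np.ndarray:
    dwell = params["dwell_means"]
    trans = params["transition"]
    out: list[np.ndarray] = []
    total = 0
    state = dominant
    while total < duration:
        run = min(int(rng.geometric(1.0 / dwell[state])), duration - total)
        out.append(np.repeat(state, run))
        total += run
        nxt = trans[state]
        targets = list(nxt)
        state = targets[rng.choice(len(targets), p=np.array([nxt[t] for t in targets]))]
    return np.concatenate(out)[:duration]


def _emit(
    rng: np.random.Generator, states: np.ndarray, em: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-second rate, etCO2, relative amplitude and waveform flag,
    each strictly on its state's side of the classifier cut-offs."""
    n = states.size
    rate = np.zeros(n)
    etco2 = np.zeros(n)
    amp = np.zeros(n)
    wave = np.ones(n, dtype=bool)

    m = states == NORMAL
    if m.any():
        mu, sd = em[NORMAL]["rate"]
        rate[m] = np.clip(rng.normal(mu, sd, m.sum()), 8.0 + _EPS, 30.0)
        mu, sd = em[NORMAL]["etco2"]
        etco2[m] = np.clip(rng.normal(mu, sd, m.sum()), 15.0, 60.0)
        amp[m] = 1.0 + rng.uniform(-0.10 + _EPS, 0.10 - _EPS, m.sum())

    m = states == HYPOPNEA
    if m.any():
        mu, sd = em[HYPOPNEA]["rate"]
        rate[m] = np.clip(rng.normal(mu, sd, m.sum()), 8.0 + _EPS, 30.0)
        mu, sd = em[HYPOPNEA]["etco2"]
        etco2[m] = np.clip(rng.normal(mu, sd, m.sum()), 10.0, 60.0)
        dev = rng.uniform(0.10 + 10 * _EPS, 0.45, m.sum())
        sign = np.where(rng.random(m.sum()) < 0.8, -1.0, 1.0)
        amp[m] = 1.0 + sign * dev

    m = states == BRADYPNEA
    if m.any():
        rate[m] = rng.uniform(2.0, 8.0 - _EPS, m.sum())
        mu, sd = em[BRADYPNEA]["etco2"]
        etco2[m] = np.clip(rng.normal(mu, sd, m.sum()), 15.0, 70.0)
        amp[m] = 1.0 + rng.uniform(-0.10 + _EPS, 0.10 - _EPS, m.sum())

    m = states == APNEA
    if m.any():
        wave[m] = False
        # rate/etco2/amp stay 0: no waveform, no CO2 return

    return rate, etco2, amp, wave


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Raw per-patient covariates with the marginal structure of an elderly
    cardiac-procedure sedation cohort; doses are correlated (r ~ 0.8)."""
    z_mid = rng.normal(size=n)
    z_extra = rng.normal(size=n)
    midazolam = np.clip(2.05 + 1.10 * z_mid, 0.5, 6.0)
    fentanyl = np.clip(
        55.4 + 24.3 * (0.8 * z_mid + np.sqrt(1 - 0.8**2) * z_extra), 12.5, 150.0
    )
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(73.0, 11.3, n), 30, 99).round(0),
            "sex": rng.choice(["F", "M"], size=n, p=[0.34, 0.66]),
            "bmi": np.clip(rng.normal(28.7, 5.4, n), 16, 55).round(1),
            "osa": rng.binomial(1, 0.25, n),
            "stop_bang": rng.choice(
                ["low", "moderate", "high"], size=n, p=[0.41, 0.27, 0.32]
            ),
            "copd": rng.binomial(1, 0.16, n),
            "smoker": rng.binomial(1, 0.41, n),
            "asa": rng.choice([1, 2, 3, 4], size=n, p=[0.11, 0.51, 0.31, 0.07]),
            "charlson": np.clip(np.round(rng.normal(5.6, 2.4, n)), 0, 15).astype(int),
            "admission_type": rng.choice(["day", "emergency"], size=n, p=[0.9, 0.1]),
            "midazolam_dose": midazolam.round(2),
            "fentanyl_dose": fentanyl.round(1),
        }
    )


def _draw_archetypes(
    rng: np.random.Generator,
    cov: pd.DataFrame,
    prevalences: tuple[float, ...],
    effects: dict[str, tuple],
) -> np.ndarray:
    """Archetype membership from a multinomial logit: per-covariate effects
    on standardized covariate values shift the logits, and the intercepts
    are calibrated (fixed-point iteration) so the cohort-average membership
    probabilities still equal the configured prevalences."""
    n = len(cov)
    target = np.asarray(prevalences, dtype=float)
    shifts = np.zeros((n, len(target)))
    for name, beta in effects.items():
        x = pd.to_numeric(cov[name], errors="coerce").to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        shifts += np.outer(z, np.asarray(beta, dtype=float))
    intercept = np.log(target + 1e-300)
    for _ in range(200):
        logits = intercept + shifts
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        mean_p = probs.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(target > 0, np.log(target / np.maximum(mean_p, 1e-300)), 0.0)
        if np.max(np.abs(step)) < 1e-10:
            break
        intercept = intercept + step
    cum = probs.cumsum(axis=1)
    u = rng.random(n)
    return (u[:, None] > cum).sum(axis=1)


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate one cohort. Deterministic given the config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    width = max(3, len(str(n)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]

    cov = _draw_covariates(rng, n)
    cov.insert(0, "patient_id", pids)
    arch_idx = _draw_archetypes(
        rng, cov, config.archetype_prevalences, config.covariate_effects
    )
    # zero-prevalence archetypes can never be drawn; keep indices as-is
    archetypes = np.asarray(ARCHETYPES, dtype=object)[arch_idx]

    durations = np.maximum(
        60,
        np.round(
            rng.lognormal(np.log(config.duration_median_s), config.duration_sigma, n)
        ).astype(int),
    )

    frames = []
    true_states: dict[str, np.ndarray] = {}
    intervention_flags = np.zeros(n, dtype=int)
    for i, pid in enumerate(pids):
        T = int(durations[i])
        arch = str(archetypes[i])
        states = _simulate_state_stream(rng, config.dwell_params[arch], T, arch)
        true_states[pid] = states
        rate, etco2, amp, wave = _emit(rng, states, config.emission_params)
        artifact = rng.random(T) < config.artifact_rate

        # SpO2: hyperoxic baseline, occasional desaturation episode
        spo2_base = np.clip(rng.normal(98.5, 0.8), 95.5, 100.0)
        spo2 = np.clip(spo2_base + rng.normal(0, 0.3, T), 85.0, 100.0)
        if rng.random() < config.desat_rate:
            dur = int(rng.integers(30, 81))
            start = int(rng.integers(0, max(1, T - dur)))
            spo2[start : start + dur] = rng.uniform(85.0, 89.5, min(dur, T - start))
        pulse = rng.random(T) >= 0.005
        spo2 = spo2.round(1)

        # TcCO2: baseline + mild sedation drift + hypoventilation burden
        abn = np.isin(states, [APNEA, BRADYPNEA, HYPOPNEA]).astype(float)
        cum_abn = np.cumsum(abn)
        # weak association by design: per-patient slope/gain heterogeneity
        # dominates the shared hypoventilation-burden signal
        tc_base = rng.normal(37.5, 4.0)
        tc_slope = rng.normal(4.0, 2.5)
        tc_gain = max(rng.normal(2.0, 2.0), 0.0)
        drift = tc_slope * np.arange(T) / T + tc_gain * cum_abn / T
        noise = np.convolve(rng.normal(0, 4.0, T), np.ones(15) / 15, mode="same")
        tcco2 = (tc_base + drift + noise).round(2)

        # interventions cluster in patients with heavy apnea burden
        apnea_frac = float(np.mean(states == APNEA))
        p_intervene = 1.0 / (1.0 + np.exp(-(-3.3 + 3.5 * apnea_frac)))
        intervention_flags[i] = int(rng.random() < p_intervene)

        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "t": np.arange(T),
                    "resp_rate": rate.round(2),
                    "etco2": etco2.round(2),
                    "rel_amplitude": amp.round(4),
                    "waveform_present": wave,
                    "artifact": artifact,
                    "spo2": spo2,
                    "pulse_detected": pulse,
                    "tcco2": tcco2,
                }
            )
        )

    cov["intervention_received"] = intervention_flags
    monitoring = pd.concat(frames, ignore_index=True)
    return SyntheticCohort(
        monitoring=monitoring,
        covariates=cov,
        true_archetype=pd.Series(archetypes, index=pd.Index(pids, name="patient_id")),
        true_states=true_states,
        config=config,
    )


def _coupled_state_stream(
    stream_seed: int, dwell: dict[str, float], trans: dict[str, dict],
    duration: int, start: str,
) -> np.ndarray:
    """Semi-Markov stream using inverse-transform geometric dwells from a
    reproducible uniform stream: with the same ``stream_seed``, the visited
    state path is identical across different dwell means, and each run's
    length is monotone in its state's mean dwell (common random numbers)."""
    rng = np.random.default_rng(stream_seed)
    out: list[np.ndarray] = []
    total = 0
    state = start
    while total < duration:
        u = rng.random()
        p = 1.0 / dwell[state]
        run = int(np.ceil(np.log1p(-u) / np.log1p(-p))) if p < 1 else 1
        run = min(max(run, 1), duration - total)
        out.append(np.repeat(state, run))
        total += run
        v = rng.random()
        nxt = trans[state]
        targets = list(nxt)
        cum = np.cumsum([nxt[t] for t in targets])
        state = targets[int(np.searchsorted(cum, v * cum[-1]))]
    return np.concatenate(out)[:duration]


def simulate_effect_cohorts(
    n_patients: int,
    dwell_multipliers: tuple[float, ...],
    seed: int,
    target_state: str = APNEA,
    duration_median_s: float = 240.0,
) -> list[tuple[SyntheticCohort, np.ndarray]]:
    """Power-experiment cohorts: a binary covariate x scales the mean dwell
    of ``target_state`` for the x=1 half of patients, at each multiplier.

    All base randomness (durations, visited state paths, the x=0 half) is
    shared across multipliers, so per patient only the target-state run
    lengths grow with the multiplier: the covariate's pseudo-R2 against the
    sequence dissimilarity matrix isolates the injected effect.
    Returns one ``(cohort, x)`` pair per multiplier, x aligned to the
    cohort's sorted patient ids.
    """
    master = np.random.default_rng(seed)
    x = (np.arange(n_patients) % 2).astype(int)
    width = max(3, len(str(n_patients)))
    pids = [f"P{i + 1:0{width}d}" for i in range(n_patients)]
    durations = np.maximum(
        60,
        np.round(
            np.exp(master.normal(np.log(duration_median_s), 0.4, n_patients))
        ).astype(int),
    )
    stream_seeds = master.integers(0, 2**31 - 1, size=n_patients)
    emit_seeds = master.integers(0, 2**31 - 1, size=n_patients)
    base_dwell = default_dwell_params()[NORMAL]
    em = default_emission_params()

    results = []
    for mult in dwell_multipliers:
        frames, states_map = [], {}
        for i, pid in enumerate(pids):
            dwell = dict(base_dwell["dwell_means"])
            if x[i] == 1:
                dwell[target_state] *= mult
            states = _coupled_state_stream(
                int(stream_seeds[i]), dwell, base_dwell["transition"],
                int(durations[i]), NORMAL,
            )
            states_map[pid] = states
            ern = np.random.default_rng(int(emit_seeds[i]))
            rate, etco2, amp, wave = _emit(ern, states, em)
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pid,
                        "t": np.arange(durations[i]),
                        "resp_rate": rate.round(2),
                        "etco2": etco2.round(2),
                        "rel_amplitude": amp.round(4),
                        "waveform_present": wave,
                        "artifact": False,
                        "spo2": 98.5,
                        "pulse_detected": True,
                        "tcco2": 38.0,
                    }
                )
            )
        cov = pd.DataFrame({"patient_id": pids, "x": x})
        cohort = SyntheticCohort(
            monitoring=pd.concat(frames, ignore_index=True),
            covariates=cov,
            true_archetype=pd.Series(
                [NORMAL] * n_patients, index=pd.Index(pids, name="patient_id")
            ),
            true_states=states_map,
            config=SyntheticCohortConfig(n_patients=n_patients, seed=seed),
        )
        results.append((cohort, x.copy()))
    return results
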
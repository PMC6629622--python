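"""End-to-end orchestration: monitoring data -> states -> distances ->
typology -> distance matrix regression, with every artifact written to an
output directory and a run log recording the config hash for reproducibility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov_mod
from . import io, states, typology
from .distance import pairwise_dissimilarity
from .dmr import bivariate_dmr, build_design, mdmra_fit
from .synth import SyntheticCohort, SyntheticCohortConfig, simulate_cohort

#: Numeric / categorical terms of the default multivariable model.
MODEL_NUMERIC = [
    "tcco2_peak", "tcco2_baseline", "age", "bmi",
    "pca_dose_1", "pca_dose_2", "charlson", "hyperoxia_s",
]
MODEL_CATEGORICAL = [
    "osa", "sex", "admission_type", "smoker", "copd",
    "intervention_received", "stop_bang",
]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; thresholds default to the
    conventional cut-offs (rate < 8, amplitude +/-10%, SpO2 >97 / <90)."""

    monitoring_csv: str | None = None
    covariates_csv: str | None = None
    synth: SyntheticCohortConfig | None = None
    metric: str = "chi2"
    n_intervals: int = 1
    k_range: tuple[int, int] = (2, 6)
    k_final: int = 4
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "results"
    rate_cutoff: float = states.RATE_CUTOFF
    amplitude_tolerance: float = states.AMPLITUDE_TOLERANCE
    spo2_high: float = 97.0
    spo2_low: float = 90.0

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        raw = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(raw.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the main
    in-memory results keyed by stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort: SyntheticCohort | None = None
    if config.synth is not None:
        cohort = simulate_cohort(config.synth)
        monitoring, covariates = cohort.monitoring, cohort.covariates
        io.write_monitoring_csv(monitoring, out / "monitoring.csv")
        io.write_covariates_csv(covariates, out / "covariates_raw.csv")
    else:
        if config.monitoring_csv is None or config.covariates_csv is None:
            raise ValueError("need either a synth config or both input CSVs")
        monitoring = io.read_monitoring_csv(config.monitoring_csv)
        covariates = io.read_covariates_csv(config.covariates_csv)

    seqs = states.sequences_from_frame(
        monitoring,
        rate_cutoff=config.rate_cutoff,
        amplitude_tolerance=config.amplitude_tolerance,
    )
    io.write_sequences_csv(seqs, out / "state_sequences.csv")

    D = pairwise_dissimilarity(seqs, metric=config.metric, n_intervals=config.n_intervals)
    io.write_distance_csv(D, out / "distance.csv")

    report = typology.quality_report(D, range(config.k_range[0], config.k_range[1] + 1))
    solution = typology.ward_cluster(D, config.k_final, seqs=seqs)
    labels_df = pd.DataFrame(
        {
            "patient_id": solution.ids,
            "cluster": solution.labels,
            "cluster_name": [solution.dominant_state.get(c, "") for c in solution.labels],
        }
    )
    labels_df.to_csv(out / "cluster_labels.csv", index=False)
    (out / "cluster_quality.json").write_text(
        json.dumps(
            {
                "per_k": {str(k): v for k, v in report.items()},
                "selected_k": typology.select_k(report),
                "final_k": config.k_final,
                "sizes": {str(c): s for c, s in solution.sizes().items()},
                "dominant_state": {
                    str(c): s for c, s in solution.dominant_state.items()
                },
            },
            indent=2,
        )
    )
    typology.sequence_index_plot(
        seqs, solution.labels, str(out / "sequence_index.png"),
        group_names={
            c: f"Type {c}: {s.lower()}" for c, s in solution.dominant_state.items()
        },
    )

    full_cov = cov_mod.derive_covariates(monitoring, covariates)
    io.write_covariates_csv(full_cov, out / "covariates.csv")
    design = build_design(full_cov, MODEL_NUMERIC, MODEL_CATEGORICAL)
    # subset/reorder D to the complete-case patients, in design order
    keep = [D.ids.index(i) for i in design.ids]
    Dm = D.values[np.ix_(keep, keep)]
    result = mdmra_fit(Dm, design, n_perm=config.n_perm, seed=config.seed)
    result.to_frame().to_csv(out / "mdmra.csv", index=False)

    hyp = full_cov.set_index("patient_id").loc[design.ids, "hypoxemia_s"]
    if hyp.std() > 0:
        bires = bivariate_dmr(
            Dm, hyp.to_numpy(dtype=float), name="hypoxemia_s",
            n_perm=config.n_perm, seed=config.seed + 1,
        )
        bires.to_frame().to_csv(out / "hypoxemia_dmr.csv", index=False)
    else:
        bires = None
        (out / "hypoxemia_dmr.csv").write_text(
            "term,pseudo_F,pseudo_R2,proportion_explained,p_value\n"
        )

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config_hash": config.digest(),
                "n_patients": len(seqs),
                "metric": config.metric,
                "n_permutations": config.n_perm,
                "seed": config.seed,
                "listwise_dropped": design.n_dropped,
            },
            indent=2,
        )
    )
    return {
        "cohort": cohort,
        "sequences": seqs,
        "distance": D,
        "quality_report": report,
        "solution": solution,
        "covariates": full_cov,
        "mdmra": result,
        "hypoxemia": bires,
    }
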
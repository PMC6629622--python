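#!/usr/bin/env python
"""Typology of respiratory state sequences by Ward clustering.

Scores candidate cluster counts k = 2..6 on the chi-squared dissimilarity
matrix, cuts the Ward tree at the final k = 4, names each cluster by its
modal state, draws the sequence index plot, and — because the cohort is
synthetic — validates recovery against the hidden archetypes.
"""

import json
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from capnoseq import io
from capnoseq.typology import quality_report, select_k, sequence_index_plot, ward_cluster

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "seq_reader", Path(__file__).parent / "03_sequence_distances.py"
)
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
read_sequences = _mod.read_sequences

OUT = Path("results")
FINAL_K = 4


def main() -> None:
    D = io.read_distance_csv(OUT / "distance.csv")
    seqs = read_sequences()

    report = quality_report(D)
    print("cluster-quality report (average silhouette width / point-biserial):")
    for k, q in report.items():
        marker = " <-" if k == select_k(report) else ""
        print(f"  k={k}: ASW {q['silhouette']:.3f}  PB {q['point_biserial']:.3f}{marker}")

    sol = ward_cluster(D, FINAL_K, seqs=seqs)
    pd.DataFrame(
        {
            "patient_id": sol.ids,
            "cluster": sol.labels,
            "cluster_name": [sol.dominant_state[c] for c in sol.labels],
        }
    ).to_csv(OUT / "cluster_labels.csv", index=False)
    (OUT / "cluster_quality.json").write_text(
        json.dumps(
            {
                "per_k": {str(k): v for k, v in report.items()},
                "selected_k": select_k(report),
                "final_k": FINAL_K,
                "sizes": {str(c): s for c, s in sol.sizes().items()},
                "dominant_state": {str(c): s for c, s in sol.dominant_state.items()},
            },
            indent=2,
        )
    )
    sequence_index_plot(
        seqs, sol.labels, str(OUT / "sequence_index.png"),
        group_names={c: f"Type {c}: {s.lower()}" for c, s in sol.dominant_state.items()},
    )

    n = sol.labels.size
    print(f"final typology at k={FINAL_K}:")
    for c in range(1, FINAL_K + 1):
        size = sol.sizes()[c]
        print(
            f"  type {c} ({sol.dominant_state[c].lower():<10}) "
            f"n={size:3d} ({100 * size / n:.0f}%)"
        )
    truth = pd.read_csv(OUT / "true_archetypes.csv", index_col=0)["archetype"]
    ari = adjusted_rand_score(truth.loc[sol.ids], sol.labels)
    print(f"adjusted Rand index vs hidden archetypes: {ari:.3f}")
    print(f"wrote cluster_labels.csv, cluster_quality.json, sequence_index.png to {OUT}/")


if __name__ == "__main__":
    main()
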
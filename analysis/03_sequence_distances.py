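#!/usr/bin/env python
"""Pairwise dissimilarities between respiratory state sequences.

Computes the primary chi-squared distance matrix (squared occupancy
differences weighted by inverse pooled state prevalence, so rare states
such as bradypnea count more) and, for comparison, the unweighted
Euclidean version; both are length-normalized through occupancy
proportions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from capnoseq import io
from capnoseq.distance import pairwise_dissimilarity
from capnoseq.states import StateSequence

OUT = Path("results")


def read_sequences():
    df = pd.read_csv(OUT / "state_sequences.csv")
    return [
        StateSequence(str(pid), g.sort_values("t")["state"].to_numpy(dtype=object))
        for pid, g in df.groupby("patient_id", sort=True)
    ]


def main() -> None:
    seqs = read_sequences()
    Dc = pairwise_dissimilarity(seqs, metric="chi2")
    De = pairwise_dissimilarity(seqs, metric="euclid")
    io.write_distance_csv(Dc, OUT / "distance.csv")
    io.write_distance_csv(De, OUT / "distance_euclid.csv")

    iu = np.triu_indices(Dc.n, 1)
    r = np.corrcoef(Dc.values[iu], De.values[iu])[0, 1]
    print(f"{Dc.n}x{Dc.n} dissimilarity matrices written (chi2 primary)")
    print("pooled state marginal (chi2 weights are its inverse):")
    for s, m in Dc.marginal.items():
        print(f"  {s:<10} {m:.3f}")
    print(f"chi2 vs euclidean distance correlation: {r:.3f}")
    print(f"wrote distance.csv (+.json sidecar), distance_euclid.csv to {OUT}/")


if __name__ == "__main__":
    main()
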
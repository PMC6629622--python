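#!/usr/bin/env python
"""Classify every monitored second into a respiratory state.

Applies the capnography cut-offs (apnea: no waveform or etCO2 = 0;
bradypnea: rate < 8/min; hypopnea: amplitude deviating > 10% from baseline;
artifact seconds marked missing) and writes the per-second state sequences.
"""

from pathlib import Path

import pandas as pd

from capnoseq import io
from capnoseq.states import STATE_ALPHABET, sequences_from_frame

OUT = Path("results")


def main() -> None:
    monitoring = io.read_monitoring_csv(OUT / "monitoring.csv")
    seqs = sequences_from_frame(monitoring)
    io.write_sequences_csv(seqs, OUT / "state_sequences.csv")

    pooled = pd.Series(
        [s for seq in seqs for s in seq.states]
    ).value_counts(normalize=True)
    print(f"classified {len(seqs)} patients")
    print("overall time-in-state (incl. missing):")
    for state in [*STATE_ALPHABET, "MISSING"]:
        print(f"  {state:<10} {100 * pooled.get(state, 0.0):5.1f}%")
    print(f"wrote state_sequences.csv to {OUT}/")


if __name__ == "__main__":
    main()
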
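"""Expand the coupling/trafficking/production rules into the concrete
reaction network and export it for inspection.

Writes results/network/: the 85-reaction table, the 32 state labels, and the
reaction-class census.
"""

from pathlib import Path

import pandas as pd

from vegfr_trafficking import expand_reactions, state_labels

OUT = Path(__file__).resolve().parents[1] / "results" / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    network = expand_reactions()
    network.to_csv(OUT / "reactions.csv")
    pd.Series(state_labels(), name="state").to_csv(OUT / "state_labels.csv")
    counts = network.class_counts()
    pd.Series(counts, name="n_reactions").to_csv(OUT / "reaction_census.csv")
    trafficking = sum(
        counts[c] for c in ("internalization", "recycle4", "transfer4to11",
                            "recycle11", "degradation")
    )
    print(f"{len(network)} reactions over {len(state_labels())} state entries:")
    print(f"  production {counts['production']}, trafficking+degradation "
          f"{trafficking}, coupling {counts['coupling']}, "
          f"uncoupling {counts['uncoupling']}")


if __name__ == "__main__":
    main()
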
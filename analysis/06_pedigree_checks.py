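#!/usr/bin/env python
"""Pedigree-arithmetic cross-checks for documented cultivars.

For cultivars with well-known pedigrees, the expected vinifera
percentage is the midparent mean of the parents' percentages; these
expectations are the classical sanity check for marker-based estimates.
Writes the worked examples under results/pedigree/.
"""

from pathlib import Path

import pandas as pd

from vitis_ancestry import midparent_percent, midparent_percent_rounded
from vitis_ancestry.pedigree import WORKED_EXAMPLES

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "pedigree"
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "cultivar": name,
            "parent1_percent": p1,
            "parent2_percent": p2,
            "midparent_percent": midparent_percent(p1, p2),
            "expected_percent": midparent_percent_rounded(p1, p2),
        }
        for name, (p1, p2) in WORKED_EXAMPLES.items()
    ]
    table = pd.DataFrame(rows)
    table.to_csv(out / "midparent_expectations.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
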
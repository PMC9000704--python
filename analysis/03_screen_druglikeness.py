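"""Apply the Lipinski rule-of-five screen to the 46 flavonoids.

Finding: under the strict all-criteria policy most of the panel passes; the
failures are the large lipophilic entries (e.g. licoagrone violates both the
500 Da mass bound and LogP ≤ 5, lutein fails on LogP). Molar refractivity is
not tabulated for these compounds, so that criterion is informational only.
"""

from pathlib import Path

import pandas as pd

from ptp1b_qsar import packaged_flavonoid_table
from ptp1b_qsar.druglikeness import lipinski_filter

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = packaged_flavonoid_table()
passing, verdicts = lipinski_filter(table, policy="strict")

df = pd.DataFrame(
    [
        {
            "index": v.index,
            "name": v.name,
            **{k: ("" if ok is None else bool(ok)) for k, ok in v.criteria.items()},
            "violations": ";".join(v.violations),
            "pass": v.passed,
        }
        for v in verdicts
    ]
)
df.to_csv(OUT / "lipinski_verdicts.csv", index=False)

print(f"{len(passing)}/{len(table)} flavonoids pass the strict rule of five")
for v in verdicts:
    if not v.passed:
        print(f"  fail: {v.index:>2} {v.name[:45]:<45} {', '.join(v.violations)}")
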
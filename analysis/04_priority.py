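"""Score clinical priority for the 58 published pola+BR signals.

Applies the default five-component rubric (report count, ROR CI lower
bound, fatal-report burden, DME/IME membership, evidence appraisal) to the
published per-signal inputs and bins totals as low (0-4), moderate (5-7)
or high (8-10).  Writes results/priority_published.csv.
"""

import pandas as pd

from _common import results_path

from polabr.clinical_priority import PriorityInputs, score_table
from polabr.reference import load_priority_inputs

rows = load_priority_inputs()
inputs = [PriorityInputs(pt=r.pt, n=int(r.n), ror025=float(r.ror025),
                         deaths=int(r.deaths),
                         ime_flag=r.medical_event == "IME",
                         dme_flag=r.medical_event == "DME",
                         evidence=r.evidence)
          for r in rows.itertuples(index=False)]
results, counts, _ = score_table(inputs)

frame = pd.DataFrame([(r.pt, r.score, r.level, *r.components.values())
                      for r in results],
                     columns=["pt", "score", "level",
                              *results[0].components])
frame = rows[["soc", "pt", "n", "ror025", "deaths"]].merge(frame, on="pt")
frame.to_csv(results_path("priority_published.csv"), index=False)

print(f"scored {len(results)} signals: "
      + ", ".join(f"{k}={v}" for k, v in counts.items()))
high = [r.pt for r in results if r.level == "high"]
print("high priority:", ", ".join(high))
print("wrote results/priority_published.csv")
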
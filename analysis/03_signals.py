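"""Run the ROR disproportionality scan on the simulated database.

Every PT with >= 10 cohort reports gets a 2x2 table against all other
deduplicated reports; a signal requires the Woolf 95% CI lower bound to
exceed 1.  With one association planted at true ROR 5, the scan should
flag it and stay quiet on the null background PTs.
Writes results/signals.csv.
"""

from importlib import resources

from _common import load_cohort, results_path

from polabr.faers_tables import load_meddra_map
from polabr.signal_ror import detect_signals, signals_to_frame

cohort, data = load_cohort()
with resources.as_file(resources.files("polabr.data")
                       / "pt_soc_map.tsv") as p:
    meddra = load_meddra_map(str(p))

signals = detect_signals(data, meddra, min_count=10)
frame = signals_to_frame(signals)
frame.to_csv(results_path("signals.csv"), index=False)

significant = frame[frame["significant"]]
print(f"PTs with >= 10 cohort reports: {len(frame)}; "
      f"significant signals: {len(significant)}")
for row in significant.itertuples(index=False):
    print(f"  {row.pt}: n={row.n} ROR={row.ror} "
          f"({row.ror_lo}-{row.ror_hi})")
print("wrote results/signals.csv")
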
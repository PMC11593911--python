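"""WGS-style inputs: a uniform fraction of all target SNPs observed.

Emulates extracting a virtual SNP panel from whole-genome sequencing, with
10% to 75% of the 20,000 targets typed.  Expectation: far higher call rates
and much lower error rates than the sparse targeted panels.
"""

from pathlib import Path

import snpimpute as si
from snpimpute.benchmark import plot_median_minmax

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = si.BenchmarkConfig()
report = si.run_fraction_benchmark(cfg)
report.write(str(OUT / "wgs_fractions"))

agg = report.aggregates
at_call = agg[agg.q_gp == cfg.call_threshold].sort_values("fraction")
print("fraction  call_rate(med)  error_rate(med)")
for _, row in at_call.iterrows():
    print(f"{row.fraction:8.2f}  {row.call_rate_median:14.3f}  {row.error_rate_median:15.5f}")
plot_median_minmax(at_call, "fraction", str(OUT / "fig_wgs_fractions.png"))
print(f"tables and figure written under {OUT}")
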
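"""Build the default synthetic reference panel and summarize what it looks like.

Writes the panel and one degraded test sample as VCF plus an LD-decay and
allele-frequency summary table, so the raw material of the study can be
inspected with standard tools (bcftools etc.).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import snpimpute as si
from snpimpute import vcf_io
from snpimpute.benchmark import child_seed
from snpimpute.synthetic_panel import mean_r2_by_distance

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cfg = si.BenchmarkConfig()
panel, gmap = si.build_panel(cfg, child_seed(cfg.master_seed, "panel", "single"))
print(f"panel: {panel.K} haplotypes x {panel.L} sites, "
      f"span {panel.sites.pos[-1] / 1e6:.1f} Mb ({panel.sites.cm[-1]:.1f} cM)")

freqs = panel.allele_freqs()
maf = np.minimum(freqs, 1 - freqs)
bins = [0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
sfs = pd.DataFrame({
    "maf_bin": [f"[{a},{b})" for a, b in zip(bins, bins[1:])],
    "n_sites": np.histogram(maf, bins=bins)[0],
})
r2 = mean_r2_by_distance(panel, [0.0, 0.05, 0.2, 0.5, 1.0, 2.0], seed=1)
ld = pd.DataFrame({"cm_bin": ["0-0.05", "0.05-0.2", "0.2-0.5", "0.5-1", "1-2"], "mean_r2": r2})
sfs.to_csv(OUT / "panel_sfs.csv", index=False)
ld.to_csv(OUT / "panel_ld_decay.csv", index=False)
print(sfs.to_string(index=False))
print(ld.round(4).to_string(index=False))

vcf_io.write_panel_vcf(panel, str(OUT / "panel.vcf"))
ind = si.sample_truth_individual(panel, seed=child_seed(cfg.master_seed, "truth", "any", 0),
                                 recombine=True, ne=cfg.ne)
obs = si.degrade(ind.genotypes, si.DegradationConfig(n_target=5000, dropin_rate=0.1, seed=2))
vcf_io.write_observed_vcf(obs, str(OUT / "sample00_degraded.vcf"))
print(f"wrote panel.vcf and sample00_degraded.vcf ({obs.n_observed} typed sites) to {OUT}")
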
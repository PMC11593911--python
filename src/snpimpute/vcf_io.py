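"""VCF round-tripping for panels, degraded targets, and imputed output.

Dialect: VCF 4.2 text, biallelic SNP records only.  Panels are fully phased
("|" separator) with the per-site genetic-map position stored as INFO CM so a
panel round-trips bit-exactly without a separate map file; targets and imputed
samples are unphased ("/") with MISSING encoded "./.".  Degraded targets carry
a single-character provenance FORMAT tag (O observed, E observed-erroneous,
M missing) so truth comparisons survive a round trip.  Imputed output uses the
conventional GT:DS:GP dialect (DS = ALT dosage, GP = three genotype
probabilities, both printed with 4 decimals).

Reading goes through cyvcf2; non-biallelic / non-SNP records are skipped with
a logged count.  There is no allele harmonization: REF/ALT mismatches between
target and panel are a hard error (harmonize inputs upstream).
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from .imputation_engine import CalledGenotypes, PosteriorField
from .types import (
    MISSING,
    PROV_CHAR,
    PROV_FROM_CHAR,
    GeneticMap,
    HaplotypePanel,
    ObservedGenotypes,
    SiteTable,
)

logger = logging.getLogger(__name__)

_HEADER = "##fileformat=VCFv4.2\n"


def _sample_names(panel: HaplotypePanel) -> list[str]:
    """Pair consecutive haplotype rows into diploid carrier samples."""
    if panel.K % 2 != 0:
        raise ValueError("panel must have an even number of haplotypes to write as VCF")
    names = []
    for s in range(panel.K // 2):
        a, b = str(panel.hap_ids[2 * s]), str(panel.hap_ids[2 * s + 1])
        if a.endswith("_0") and b.endswith("_1") and a[:-2] == b[:-2]:
            names.append(a[:-2])
        else:
            names.append(f"S{s:04d}")
    if len(set(names)) != len(names):
        names = [f"S{s:04d}" for s in range(panel.K // 2)]
    return names


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write a phased panel; population labels go into ##SAMPLE header lines."""
    names = _sample_names(panel)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={panel.sites.chrom}>\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=String,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for s, name in enumerate(names):
            fh.write(f"##SAMPLE=<ID={name},Population={panel.pop_labels[2 * s]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        sites = panel.sites
        for m in range(panel.L):
            gts = "\t".join(
                f"{panel.alleles[2 * s, m]}|{panel.alleles[2 * s + 1, m]}"
                for s in range(panel.K // 2)
            )
            fh.write(
                f"{sites.chrom}\t{sites.pos[m]}\t.\t{sites.ref[m]}\t{sites.alt[m]}\t.\t.\t"
                f"CM={float(sites.cm[m])!r}\tGT\t{gts}\n"
            )


def read_panel_vcf(
    path: str, region: tuple[str, int, int] | None = None
) -> HaplotypePanel:
    """Read a fully phased panel; K = 2 x n_samples, site order = file order.

    region, if given, is (chrom, start, end) with 1-based inclusive bounds.
    Non-biallelic or non-SNP records are skipped (count logged); an unphased or
    missing genotype is a hard error naming the record.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    pop_by_sample = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##SAMPLE=<"):
            fields = dict(
                kv.split("=", 1) for kv in line[len("##SAMPLE=<") : -1].split(",")
            )
            if "ID" in fields and "Population" in fields:
                pop_by_sample[fields["ID"]] = fields["Population"]
    chrom = None
    pos, ref, alt, cm, cols = [], [], [], [], []
    skipped = 0
    for var in vcf:
        if region is not None:
            rc, rs, re_ = region
            if var.CHROM != rc or not (rs <= var.POS <= re_):
                continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("multi-chromosome panels are not supported in one read")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for s, gt in enumerate(var.genotypes):
            a1, a2, phased = gt[0], gt[1], gt[-1]
            if a1 < 0 or a2 < 0:
                raise ValueError(f"missing genotype at {var.CHROM}:{var.POS} sample {samples[s]}")
            if not phased:
                raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS} sample {samples[s]}")
            col[2 * s] = a1
            col[2 * s + 1] = a2
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        info_cm = var.INFO.get("CM")
        cm.append(float(info_cm) if info_cm is not None else 0.0)
        cols.append(col)
    if skipped:
        logger.info("read_panel_vcf: skipped %d non-biallelic-SNP records", skipped)
    alleles = np.array(cols, dtype=np.uint8).T if cols else np.zeros((2 * len(samples), 0), np.uint8)
    sites = SiteTable(chrom or "NA", np.array(pos, dtype=np.int64), ref, alt, cm)
    labels = np.array(
        [pop_by_sample.get(s, "pop1") for s in samples for _ in range(2)], dtype=object
    )
    hap_ids = np.array([f"{s}_{h}" for s in samples for h in (0, 1)], dtype=object)
    return HaplotypePanel(sites, alleles, labels, hap_ids)


def exclude_samples(panel: HaplotypePanel, sample_ids) -> HaplotypePanel:
    """Remove both haplotypes of each named diploid sample."""
    drop = []
    for sid in sample_ids:
        rows = [
            k
            for k in range(panel.K)
            if str(panel.hap_ids[k]) in (f"{sid}_0", f"{sid}_1")
        ]
        if len(rows) != 2:
            raise ValueError(f"unknown sample id {sid!r}")
        drop.extend(rows)
    return panel.exclude_rows(drop)


def write_observed_vcf(obs: ObservedGenotypes, path: str, sample: str = "TARGET") -> None:
    """Write a degraded target: unphased GT plus provenance FORMAT tag PV."""
    prov = obs.provenance()
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={obs.sites.chrom}>\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=String,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PV,Number=1,Type=String,Description="Provenance O/E/M">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        s = obs.sites
        for m in range(obs.L):
            g = obs.g_obs[m]
            gt = "./." if g == MISSING else ("0/0", "0/1", "1/1")[g]
            fh.write(
                f"{s.chrom}\t{s.pos[m]}\t.\t{s.ref[m]}\t{s.alt[m]}\t.\t.\t"
                f"CM={float(s.cm[m])!r}\tGT:PV\t{gt}:{PROV_CHAR[int(prov[m])]}\n"
            )


def read_observed_vcf(path: str) -> ObservedGenotypes:
    vcf = VCF(path)
    if len(vcf.samples) != 1:
        raise ValueError("expected a single-sample target VCF")
    chrom, pos, ref, alt, cm, gs, prov = None, [], [], [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        chrom = chrom or var.CHROM
        a1, a2 = var.genotypes[0][0], var.genotypes[0][1]
        gs.append(MISSING if a1 < 0 or a2 < 0 else a1 + a2)
        pv = var.format("PV")
        prov.append(PROV_FROM_CHAR[str(pv[0])] if pv is not None else None)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        info_cm = var.INFO.get("CM")
        cm.append(float(info_cm) if info_cm is not None else 0.0)
    if skipped:
        logger.info("read_observed_vcf: skipped %d non-biallelic-SNP records", skipped)
    sites = SiteTable(chrom or "NA", np.array(pos, dtype=np.int64), ref, alt, cm)
    stored = (
        np.array([p for p in prov], dtype=np.int8) if all(p is not None for p in prov) else None
    )
    return ObservedGenotypes(sites, np.array(gs, dtype=np.int8), truth=None, stored_provenance=stored)


def write_imputed_vcf(
    called: CalledGenotypes, post: PosteriorField, path: str, sample: str = "TARGET"
) -> None:
    """Write imputation output as GT:DS:GP (4-decimal DS/GP); uncalled "./."."""
    if post.L != len(called.genotype):
        raise ValueError("posterior/called length mismatch")
    s = called.sites
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(f"##contig=<ID={s.chrom}>\n")
        if called.q_gp == called.q_gp:  # not NaN
            fh.write(f"##imputation_gp_threshold={float(called.q_gp)!r}\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=String,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype probabilities">\n')
        fh.write('##FORMAT=<ID=SC,Number=1,Type=String,Description="Call source O/I/N">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        ds = post.dosage
        src_char = {-1: "N", 0: "O", 1: "I"}
        for m in range(post.L):
            g = called.genotype[m]
            gt = "./." if g == MISSING else ("0/0", "0/1", "1/1")[g]
            gp = ",".join(f"{post.p[m, k]:.4f}" for k in range(3))
            fh.write(
                f"{s.chrom}\t{s.pos[m]}\t.\t{s.ref[m]}\t{s.alt[m]}\t.\t.\t"
                f"CM={float(s.cm[m])!r}\tGT:DS:GP:SC\t{gt}:{ds[m]:.4f}:{gp}:"
                f"{src_char[int(called.source[m])]}\n"
            )


def read_imputed_vcf(path: str) -> tuple[CalledGenotypes, PosteriorField]:
    vcf = VCF(path)
    if len(vcf.samples) != 1:
        raise ValueError("expected a single-sample imputed VCF")
    q_gp = float("nan")
    for line in vcf.raw_header.splitlines():
        if line.startswith("##imputation_gp_threshold="):
            q_gp = float(line.split("=", 1)[1])
    chrom, pos, ref, alt, cm = None, [], [], [], []
    gs, srcs, gps, probs = [], [], [], []
    src_code = {"N": -1, "O": 0, "I": 1}
    for var in vcf:
        chrom = chrom or var.CHROM
        a1, a2 = var.genotypes[0][0], var.genotypes[0][1]
        gs.append(MISSING if a1 < 0 or a2 < 0 else a1 + a2)
        p3 = np.asarray(var.format("GP")[0], dtype=float)
        probs.append(p3)
        srcs.append(src_code[str(var.format("SC")[0])])
        gps.append(float(p3.max()))
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        info_cm = var.INFO.get("CM")
        cm.append(float(info_cm) if info_cm is not None else 0.0)
    sites = SiteTable(chrom or "NA", np.array(pos, dtype=np.int64), ref, alt, cm)
    source = np.array(srcs, dtype=np.int8)
    gp_arr = np.array(gps)
    gp_arr[source == 0] = 1.0
    called = CalledGenotypes(sites, np.array(gs, dtype=np.int8), source, gp_arr, q_gp)
    return called, PosteriorField(np.array(probs) if probs else np.zeros((0, 3)))


def read_genetic_map(path: str, fmt: str = "auto") -> GeneticMap:
    """Read a genetic map.

    Supported formats: HapMap-style text with a header line and columns
    (chrom, pos_bp, rate_cM_per_Mb, cM), or the internal two-column
    "pos_bp cm" knot format.  fmt="auto" sniffs the column count.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                float(parts[-1])
            except ValueError:
                continue  # header line
            rows.append(parts)
    if not rows:
        raise ValueError(f"no map rows in {path}")
    ncol = len(rows[0])
    if fmt == "auto":
        fmt = "hapmap" if ncol >= 3 else "knots"
    if fmt == "hapmap":
        pos = np.array([float(r[-3]) for r in rows])
        cm = np.array([float(r[-1]) for r in rows])
    elif fmt == "knots":
        pos = np.array([float(r[0]) for r in rows])
        cm = np.array([float(r[1]) for r in rows])
    else:
        raise ValueError(f"unknown map format {fmt!r}")
    return GeneticMap(pos, cm)


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        for p, c in zip(gmap.pos, gmap.cm):
            fh.write(f"{float(p)!r} {float(c)!r}\n")
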
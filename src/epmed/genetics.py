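"""Genotype I/O, allele frequencies, Hardy-Weinberg tests and model coding.

The association model uses one numeric predictor per marker.  Markers whose
minor-allele frequency (computed in the unrelated subjects only) is at or
above 35% are coded additively as minor-allele dosage 0/1/2; rarer markers
are coded as presence/absence of the minor allele (0/1, dominant model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markers import DEFAULT_VARIANTS, VariantInfo, hwe_alpha

log = logging.getLogger(__name__)

MAF_ADDITIVE_THRESHOLD = 0.35


@dataclass
class GenotypeMatrix:
    """Subjects x markers minor-allele counts (0/1/2, NaN = missing call)."""

    dosage: pd.DataFrame  # index: subject id, columns: marker id
    variants: list[VariantInfo]

    def __post_init__(self) -> None:
        ids = [v.marker for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in variant registry")
        if list(self.dosage.columns) != ids:
            raise ValueError("dosage columns do not match variant registry order")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")

    @property
    def markers(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.dosage.index


@dataclass
class CodedGenotypes:
    """Model-coded genotype predictors with per-marker coding provenance."""

    values: pd.DataFrame
    coding_model: dict[str, str] = field(default_factory=dict)  # additive3|dominant2
    maf: dict[str, float] = field(default_factory=dict)


def write_genotypes_csv(G: GenotypeMatrix, path) -> None:
    G.dosage.to_csv(path, index_label="subject_id")


def write_variants_csv(variants: list[VariantInfo], path) -> None:
    pd.DataFrame(
        [
            dict(marker=v.marker, gene=v.gene, major=v.major, minor=v.minor,
                 maf=v.maf, is_deletion=v.is_deletion)
            for v in variants
        ]
    ).to_csv(path, index=False)


def read_variants_csv(path) -> list[VariantInfo]:
    df = pd.read_csv(path)
    return [
        VariantInfo(r.marker, r.gene, str(r.major), str(r.minor), float(r.maf),
                    bool(r.is_deletion))
        for r in df.itertuples()
    ]


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields.

    REF is the major allele, ALT the minor allele; the dosage is the
    ALT-allele count.  Markers are placed on a synthetic contig at
    consecutive positions (real coordinates are not tracked here).
    """
    subjects = list(G.subjects.astype(str))
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=panel>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects),
    ]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, v in enumerate(G.variants):
        # symbolic alleles (deletion, "-") are not valid VCF bases; encode as N/D
        ref = v.major if v.major.isalpha() and v.major != "ins" else "N"
        alt = v.minor if v.minor.isalpha() and v.minor != "del" else "D"
        calls = [
            gt_map.get(float(x), "./.") if not np.isnan(x) else "./."
            for x in G.dosage[v.marker].to_numpy(dtype=float)
        ]
        lines.append(
            f"panel\t{j + 1}\t{v.marker}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(calls)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_vcf(path) -> tuple[pd.DataFrame, list[VariantInfo], dict[str, str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    variants: list[VariantInfo] = []
    flipped: dict[str, str] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"marker {var.ID or f'{var.CHROM}:{var.POS}'} is not biallelic "
                f"(ALT alleles: {var.ALT})"
            )
        mid = var.ID or f"{var.CHROM}:{var.POS}"
        if mid in cols:
            raise ValueError(f"duplicate marker id {mid!r} in VCF")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        alt_count = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        called = ~np.isnan(alt_count)
        alt_freq = alt_count[called].sum() / (2 * called.sum()) if called.any() else 0.0
        ref, alt = var.REF, var.ALT[0]
        if alt_freq < 0.5 or (alt_freq == 0.5 and alt <= ref):
            major, minor, dosage = ref, alt, alt_count
        else:
            major, minor, dosage = alt, ref, 2.0 - alt_count
            flipped[mid] = f"ALT {alt} is the major allele (freq {alt_freq:.3f})"
            log.info("marker %s: minor allele is REF (%s)", mid, flipped[mid])
        if alt_freq == 0.5:
            log.info("marker %s: allele frequency tie, minor chosen lexicographically", mid)
        maf = min(alt_freq, 1.0 - alt_freq)
        variants.append(VariantInfo(mid, _gene_of(mid), major, minor, maf,
                                    is_deletion=(mid == "READ1")))
        cols[mid] = dosage
    dosage = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    return dosage, variants, flipped


def _gene_of(marker: str) -> str:
    for v in DEFAULT_VARIANTS:
        if v.marker == marker:
            return v.gene
    return "GRIN2B"  # unknown markers need *a* gene label; callers may override


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype table from VCF or CSV dosage matrix.

    CSV input is a subjects x markers dosage matrix as written by
    :func:`write_genotypes_csv`; a ``*.variants.csv`` sidecar (if present)
    supplies allele metadata, otherwise the default panel metadata is used
    for known markers.
    """
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith(".vcf") else "csv"
    if format == "vcf":
        dosage, variants, _ = _read_vcf(path)
        return GenotypeMatrix(dosage, variants)
    if format == "csv":
        dosage = pd.read_csv(path, index_col="subject_id")
        known = {v.marker: v for v in DEFAULT_VARIANTS}
        variants = []
        for m in dosage.columns:
            if m in known:
                variants.append(known[m])
            else:
                variants.append(VariantInfo(m, _gene_of(m), "A", "B",
                                            _csv_maf(dosage[m])))
        return GenotypeMatrix(dosage.astype(float), variants)
    raise ValueError(f"unknown genotype format {format!r}")


def _csv_maf(col: pd.Series) -> float:
    x = col.to_numpy(dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return 0.0
    return min(float(x.sum() / (2 * x.size)), 0.5)


def allele_frequencies(G: GenotypeMatrix, subset=None) -> pd.Series:
    """Per-marker frequency of the designated minor allele.

    MAF = (2*n_hom_minor + n_het) / (2*n_called), missing calls excluded
    from the denominator.  ``subset`` restricts to a boolean mask or list of
    subject ids (the convention is to use unrelated subjects only).
    """
    dos = G.dosage
    if subset is not None:
        dos = dos.loc[subset] if not isinstance(subset, (pd.Series, np.ndarray)) else dos[np.asarray(subset, dtype=bool)]
    if len(dos) == 0:
        raise ValueError("subject subset is empty")
    x = dos.to_numpy(dtype=float)
    called = (~np.isnan(x)).sum(axis=0)
    if (called == 0).any():
        bad = [m for m, c in zip(dos.columns, called) if c == 0]
        raise ValueError(f"no called genotypes for markers {bad}")
    freq = np.nansum(x, axis=0) / (2 * called)
    return pd.Series(freq, index=dos.columns, name="maf")


def hwe_test(counts, exact: bool = False):
    """Hardy-Weinberg equilibrium test from genotype counts.

    Parameters
    ----------
    counts : (n_AA, n_Aa, n_aa) with a = minor allele.
    exact : use the exact conditional test instead of the 1-df chi-square.

    Returns
    -------
    (chi2, df, p) — for the exact test chi2 is NaN and df is 0.
    """
    n_aa_maj, n_het, n_aa_min = (int(c) for c in counts)
    if min(n_aa_maj, n_het, n_aa_min) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_maj + n_het + n_aa_min
    if n == 0:
        raise ValueError("total genotype count is zero")
    q = (2 * n_aa_min + n_het) / (2 * n)
    if q == 0.0 or q == 1.0:
        warnings.warn("monomorphic marker: HWE test undefined, returning p=1",
                      stacklevel=2)
        return (0.0, 1, 1.0) if not exact else (float("nan"), 0, 1.0)
    if exact:
        return float("nan"), 0, _hwe_exact_p(n_het, n_aa_min, n)
    p_maj = 1.0 - q
    expected = np.array([n * p_maj**2, 2 * n * p_maj * q, n * q**2])
    observed = np.array([n_aa_maj, n_het, n_aa_min], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, pval


def _hwe_exact_p(n_het: int, n_hom_min: int, n: int) -> float:
    """Exact HWE p-value: total probability of heterozygote counts at most
    as probable as the observed one, conditional on allele counts."""
    n_minor = 2 * n_hom_min + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = {}
    from math import lgamma, log

    def logprob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            h * log(2.0)
            + lgamma(n + 1) - lgamma(hom_maj + 1) - lgamma(h + 1) - lgamma(hom_min + 1)
            - (lgamma(2 * n + 1) - lgamma(n_minor + 1) - lgamma(2 * n - n_minor + 1))
        )

    for h in hets:
        logs[h] = logprob(h)
    obs_h = n_het if n_het in logs else min(logs, key=lambda h: abs(h - n_het))
    probs = {h: np.exp(lp) for h, lp in logs.items()}
    p_obs = probs[obs_h]
    return float(min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))))


def code_genotypes(
    G: GenotypeMatrix,
    maf: pd.Series | None = None,
    maf_threshold: float = MAF_ADDITIVE_THRESHOLD,
    unrelated=None,
) -> CodedGenotypes:
    """Code each marker per the MAF >= threshold rule.

    MAF at or above the threshold: additive dosage 0/1/2 (three-level);
    below: presence/absence of the minor allele (0/1, two-level).  ``maf``
    may be supplied precomputed (e.g. on the unrelated subset); otherwise it
    is computed here, restricted to ``unrelated`` when given.
    """
    if maf is None:
        maf = allele_frequencies(G, subset=unrelated)
    values = {}
    models = {}
    for m in G.markers:
        x = G.dosage[m].to_numpy(dtype=float)
        if maf[m] >= maf_threshold:
            models[m] = "additive3"
            values[m] = x
        else:
            models[m] = "dominant2"
            values[m] = np.where(np.isnan(x), np.nan, (x > 0).astype(float))
        log.info("marker %s: MAF %.3f -> %s", m, maf[m], models[m])
    return CodedGenotypes(
        pd.DataFrame(values, index=G.subjects), models, {m: float(maf[m]) for m in G.markers}
    )


def qc_report(G: GenotypeMatrix, unrelated=None, exact: bool = False) -> pd.DataFrame:
    """Per-marker QC table: alleles, MAF, HWE p-value, per-gene threshold, flag.

    Mirrors the usual candidate-gene QC layout; the significance flag uses
    the per-gene Bonferroni threshold 0.05 / (markers in gene).
    """
    maf = allele_frequencies(G, subset=unrelated)
    dos = G.dosage if unrelated is None else G.dosage.loc[unrelated]
    rows = []
    for v in G.variants:
        x = dos[v.marker].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        counts = (int((x == 0).sum()), int((x == 1).sum()), int((x == 2).sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi2, df, p = hwe_test(counts, exact=exact)
        thr = hwe_alpha(v.gene, G.variants)
        rows.append(
            dict(marker=v.marker, gene=v.gene, major=v.major, minor=v.minor,
                 maf=float(maf[v.marker]), hwe_chi2=chi2, hwe_p=p,
                 hwe_threshold=thr, hwe_flag=bool(p < thr),
                 coding="additive3" if maf[v.marker] >= MAF_ADDITIVE_THRESHOLD
                 else "dominant2")
        )
    return pd.DataFrame(rows)
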
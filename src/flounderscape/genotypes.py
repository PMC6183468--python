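"""Genotype containers, VCF I/O, the SNP filtering cascade, and basic
population-genetic summaries (Hardy-Weinberg exact test, genotype PCA,
Weir-Cockerham FST).

The filtering cascade mirrors a standard ddRAD quality-control recipe for
FreeBayes-style calls: discovery-stage call-rate/minor-allele-count
screens, per-genotype depth recoding, removal of poorly sequenced
individuals, and per-site screens on call rate, minor allele frequency,
mean depth, heterozygote allele balance, quality/depth ratio, mapping-
quality ratio between alleles, and two high-depth rules.  Each rule is
applied in a fixed, logged order and reports how many sites it removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import EmptyResultError, InvalidParameterError, VcfParseError

logger = logging.getLogger(__name__)

MISSING = -1


# ---------------------------------------------------------------------------
# containers

@dataclass
class VariantRecord:
    """Per-site call metadata needed by the filtering rules."""

    contig: str
    position: int
    ref: str = "A"
    alt: str = "T"
    qual: float = np.nan
    #: per-individual read depth at this site (np.nan where unknown)
    depths: np.ndarray | None = None
    #: mean fraction of alternate reads at heterozygous genotypes
    allele_balance: float = np.nan
    #: mean mapping quality of alternate-supporting reads
    mqm: float = np.nan
    #: mean mapping quality of reference-supporting reads
    mqmr: float = np.nan

    def __post_init__(self):
        if self.position < 1:
            raise InvalidParameterError("position must be >= 1")


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of minor/alternate-allele dosages.

    ``dosages`` holds 0/1/2 with :data:`MISSING` (-1) for no-calls.
    ``loci`` must carry ``contig`` and ``position`` columns; ``samples``
    must carry an ``id`` column and may carry ``lat``, ``lon``, ``deme``
    and environmental columns.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise InvalidParameterError("dosages must be 2-D")
        n, L = self.dosages.shape
        if len(self.samples) != n:
            raise InvalidParameterError(
                f"sample metadata rows ({len(self.samples)}) != matrix rows ({n})")
        if len(self.loci) != L:
            raise InvalidParameterError(
                f"locus metadata rows ({len(self.loci)}) != matrix columns ({L})")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise InvalidParameterError("dosages must be 0, 1, 2 or -1")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def alt_allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over called genotypes."""
        d = self.dosages
        called = d != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def minor_allele_count(self) -> np.ndarray:
        d = self.dosages
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        return np.minimum(alt, tot - alt)

    def call_rate(self) -> np.ndarray:
        return (~self.missing_mask).mean(axis=0)

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.dosages[index],
                              self.loci.reset_index(drop=True),
                              self.samples.iloc[index].reset_index(drop=True))

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.dosages[:, index],
                              self.loci.iloc[index].reset_index(drop=True),
                              self.samples.reset_index(drop=True))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.loci.copy(),
                              self.samples.copy())


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNP filtering cascade (inclusive where phrased
    'at least'/'of X')."""

    min_call_rate_initial: float = 0.50
    min_minor_allele_count: int = 3
    min_genotype_depth: int = 3
    max_individual_missing: float = 0.77
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_mean_depth: float = 20.0
    min_het_allele_balance: float = 0.25
    min_qual_over_depth: float = 0.2
    mapq_ratio_bounds: tuple[float, float] = (0.25, 1.75)
    mean_depth_upper_quantile: float = 0.95
    hwe_alpha: float = 0.01

    def __post_init__(self):
        for name in ("min_call_rate_initial", "max_individual_missing",
                     "min_call_rate", "mean_depth_upper_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.min_maf < 0.5:
            raise InvalidParameterError("min_maf must lie in [0, 0.5)")
        lo, hi = self.mapq_ratio_bounds
        if lo >= hi:
            raise InvalidParameterError("mapq_ratio_bounds must be ordered")


@dataclass
class FilterAudit:
    """Per-rule removal bookkeeping from :func:`filter_variants`."""

    log: pd.DataFrame
    records: list[VariantRecord]
    realized_mean_depth_cutoff: float = np.nan
    skipped_rules: list[str] = field(default_factory=list)
    removed_individuals: list[str] = field(default_factory=list)

    def removed_total(self) -> int:
        return int(self.log["removed"].sum())


# ---------------------------------------------------------------------------
# VCF I/O

def _find_malformed_line(path: str) -> int | None:
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                if len(line.rstrip("\n").split("\t")) < 8:
                    return i
    except OSError:
        return None
    return None


def read_vcf(path: str) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read bi-allelic SNPs from a VCF 4.x file.

    Multi-allelic records are skipped (count logged).  Absent DP/QUAL/
    INFO fields are stored as NaN, which disables the corresponding
    filter rules downstream.
    """
    bad_line = _find_malformed_line(path)
    if bad_line is not None:
        raise VcfParseError(f"could not parse VCF {path!r}: malformed "
                            f"record at line {bad_line}")
    try:
        vcf = VCF(path)
        ids = list(vcf.samples)
        dosages, records = [], []
        n_multi = 0
        for v in vcf:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = v.gt_types
            dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2],
                            default=MISSING).astype(np.int8)
            try:
                dp = v.format("DP")
                dp = (None if dp is None
                      else np.where(dp < 0, np.nan, dp).astype(float).ravel())
            except KeyError:
                dp = None
            info = dict(v.INFO)
            records.append(VariantRecord(
                contig=v.CHROM, position=v.POS, ref=v.REF, alt=v.ALT[0],
                qual=np.nan if v.QUAL is None else float(v.QUAL),
                depths=dp,
                allele_balance=float(info.get("AB", np.nan)),
                mqm=float(info.get("MQM", np.nan)),
                mqmr=float(info.get("MQMR", np.nan))))
            dosages.append(dos)
    except VcfParseError:
        raise
    except Exception as exc:
        line = _find_malformed_line(path)
        where = f" (first malformed line: {line})" if line else ""
        raise VcfParseError(f"could not parse VCF {path!r}{where}: {exc}") from exc
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)
    dos = (np.array(dosages, dtype=np.int8).T if dosages
           else np.zeros((len(ids), 0), dtype=np.int8))
    loci = pd.DataFrame({"contig": [r.contig for r in records],
                         "position": [r.position for r in records]})
    samples = pd.DataFrame({"id": ids})
    return GenotypeMatrix(dos, loci, samples), records


_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AB,Number=1,Type=Float,Description="Mean allele balance at heterozygous genotypes">
##INFO=<ID=MQM,Number=1,Type=Float,Description="Mean mapping quality of alternate-supporting reads">
##INFO=<ID=MQMR,Number=1,Type=Float,Description="Mean mapping quality of reference-supporting reads">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(matrix: GenotypeMatrix,
              records: list[VariantRecord] | None,
              path: str) -> None:
    """Write a GT(+DP) VCF 4.2 file; the inverse of :func:`read_vcf`."""
    if records is not None and len(records) != matrix.n_loci:
        raise InvalidParameterError("records length must match locus count")
    contigs = (list(dict.fromkeys(r.contig for r in records))
               if records is not None else matrix.loci["contig"].unique())
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in matrix.samples["id"]) + "\n")
        for j in range(matrix.n_loci):
            if records is not None:
                r = records[j]
                info_items = []
                for key, val in (("AB", r.allele_balance), ("MQM", r.mqm),
                                 ("MQMR", r.mqmr)):
                    if np.isfinite(val):
                        info_items.append(f"{key}={val:g}")
                info = ";".join(info_items) or "."
                qual = "." if not np.isfinite(r.qual) else f"{r.qual:g}"
                ref, alt = r.ref, r.alt
                contig, pos = r.contig, r.position
                dp = r.depths
            else:
                contig = str(matrix.loci["contig"].iloc[j])
                pos = int(matrix.loci["position"].iloc[j])
                ref, alt, qual, info, dp = "A", "T", ".", ".", None
            fmt = "GT" if dp is None else "GT:DP"
            cells = []
            for i in range(matrix.n_individuals):
                g = _GT_CODES[int(matrix.dosages[i, j])]
                if dp is not None:
                    d = dp[i]
                    g += ":." if not np.isfinite(d) else f":{int(d)}"
                cells.append(g)
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\t"
                     f"{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# filtering cascade

def recode_low_depth(matrix: GenotypeMatrix,
                     records: list[VariantRecord],
                     min_depth: int = 3) -> GenotypeMatrix:
    """Set genotypes supported by fewer than ``min_depth`` reads to missing."""
    out = matrix.copy()
    for j, r in enumerate(records):
        if r.depths is None:
            continue
        low = np.isfinite(r.depths) & (r.depths < min_depth)
        out.dosages[low, j] = MISSING
    return out


def filter_individuals(matrix: GenotypeMatrix,
                       max_missing: float = 0.77) -> GenotypeMatrix:
    """Drop individuals whose missing-genotype fraction exceeds the cap."""
    frac = matrix.missing_mask.mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == 0:
        raise EmptyResultError("all individuals exceed the missingness cap")
    return matrix.take_individuals(keep)


def _site_mean_depths(records: list[VariantRecord]) -> np.ndarray:
    out = np.full(len(records), np.nan)
    for j, r in enumerate(records):
        if r.depths is not None and np.isfinite(r.depths).any():
            out[j] = np.nanmean(r.depths)
    return out


def _site_total_depths(records: list[VariantRecord]) -> np.ndarray:
    out = np.full(len(records), np.nan)
    for j, r in enumerate(records):
        if r.depths is not None and np.isfinite(r.depths).any():
            out[j] = np.nansum(r.depths)
    return out


def filter_variants(matrix: GenotypeMatrix,
                    records: list[VariantRecord],
                    config: FilterConfig = FilterConfig()
                    ) -> tuple[GenotypeMatrix, FilterAudit]:
    """Apply the full SNP quality cascade in its fixed order.

    Order: initial call-rate and minor-allele-count screens, low-depth
    genotype recoding, removal of high-missingness individuals, then the
    site screens (call rate, MAF, minimum mean depth, heterozygote
    allele balance, QUAL/depth, mapping-quality ratio, depth >
    mean + SD with QUAL < 2 x depth, and the upper mean-depth
    quantile).  Rules whose source field is absent are skipped with a
    warning.  Returns the filtered matrix and a :class:`FilterAudit`
    whose removal counts sum to (input loci - output loci).
    """
    if len(records) != matrix.n_loci:
        raise InvalidParameterError("records length must match locus count")
    mat = matrix
    recs = list(records)
    entries: list[tuple[str, int, int]] = []
    skipped: list[str] = []

    def apply_rule(name: str, keep: np.ndarray):
        nonlocal mat, recs
        keep = np.asarray(keep, bool)
        removed = int((~keep).sum())
        mat = mat.take_loci(np.flatnonzero(keep))
        recs = [r for r, k in zip(recs, keep) if k]
        entries.append((name, removed, mat.n_loci))

    def have(vals: np.ndarray, rule: str) -> bool:
        if not np.isfinite(vals).any() and len(vals):
            logger.warning("rule %r skipped: required field absent", rule)
            skipped.append(rule)
            entries.append((rule, 0, mat.n_loci))
            return False
        return True

    # 1-2: discovery-stage screens
    apply_rule("call_rate_initial",
               mat.call_rate() >= config.min_call_rate_initial)
    apply_rule("minor_allele_count",
               mat.minor_allele_count() >= config.min_minor_allele_count)

    # 3: recode genotypes with too few reads
    mat = recode_low_depth(mat, recs, config.min_genotype_depth)
    entries.append(("recode_low_depth", 0, mat.n_loci))

    # 4: drop high-missingness individuals
    n_before = mat.n_individuals
    frac = mat.missing_mask.mean(axis=1)
    dropped_ids = list(mat.samples["id"][frac > config.max_individual_missing])
    mat = filter_individuals(mat, config.max_individual_missing)
    entries.append(("individual_missingness", 0, mat.n_loci))
    if mat.n_individuals < n_before:
        logger.info("removed %d individuals with missingness > %.2f",
                    n_before - mat.n_individuals,
                    config.max_individual_missing)

    # 5-7: call rate / MAF / minimum mean depth
    apply_rule("call_rate", mat.call_rate() >= config.min_call_rate)
    apply_rule("maf", mat.minor_allele_freq() >= config.min_maf)
    mean_dp = _site_mean_depths(recs)
    if have(mean_dp, "mean_depth_min"):
        apply_rule("mean_depth_min",
                   ~(mean_dp < config.min_mean_depth))

    # 8: heterozygote allele balance (sites with no heterozygotes pass)
    ab = np.array([r.allele_balance for r in recs])
    if have(ab, "allele_balance"):
        apply_rule("allele_balance",
                   ~(np.isfinite(ab) & (ab < config.min_het_allele_balance)))

    # 9: QUAL / total depth
    qual = np.array([r.qual for r in recs])
    tot_dp = _site_total_depths(recs)
    ratio = qual / tot_dp
    if have(ratio, "qual_depth_ratio"):
        apply_rule("qual_depth_ratio",
                   ~(np.isfinite(ratio) & (ratio < config.min_qual_over_depth)))

    # 10: mapping-quality ratio between alternate and reference reads
    mqm = np.array([r.mqm for r in recs])
    mqmr = np.array([r.mqmr for r in recs])
    mq_ratio = mqm / mqmr
    if have(mq_ratio, "mapq_ratio"):
        lo, hi = config.mapq_ratio_bounds
        apply_rule("mapq_ratio",
                   ~(np.isfinite(mq_ratio) & ((mq_ratio < lo) | (mq_ratio > hi))))

    # 11: unusually deep sites with weak quality support
    qual = np.array([r.qual for r in recs])
    tot_dp = _site_total_depths(recs)
    if have(tot_dp, "high_depth_qual"):
        mu, sd = np.nanmean(tot_dp), np.nanstd(tot_dp)
        deep = np.isfinite(tot_dp) & (tot_dp > mu + sd)
        weak = np.isfinite(qual) & (qual < 2.0 * tot_dp)
        apply_rule("high_depth_qual", ~(deep & weak))

    # 12: keep the lower quantile of the mean-depth distribution
    mean_dp = _site_mean_depths(recs)
    cutoff = np.nan
    if have(mean_dp, "mean_depth_quantile"):
        cutoff = float(np.nanquantile(mean_dp,
                                      config.mean_depth_upper_quantile))
        apply_rule("mean_depth_quantile",
                   ~(np.isfinite(mean_dp) & (mean_dp > cutoff)))

    log = pd.DataFrame(entries, columns=["rule", "removed", "remaining"])
    audit = FilterAudit(log=log, records=recs,
                        realized_mean_depth_cutoff=cutoff,
                        skipped_rules=skipped,
                        removed_individuals=dropped_ids)
    return mat, audit


def one_snp_per_contig(matrix: GenotypeMatrix,
                       records: list[VariantRecord] | None = None
                       ) -> GenotypeMatrix:
    """Keep only the lowest-position SNP on each contig (unlinked panel)."""
    loci = matrix.loci
    order = np.lexsort((loci["position"].to_numpy(),
                        loci["contig"].to_numpy()))
    if not np.array_equal(order, np.arange(len(loci))):
        logger.info("loci were not sorted by (contig, position); "
                    "sorting internally")
    first = {}
    for idx in order:
        c = loci["contig"].iloc[idx]
        if c not in first:
            first[c] = idx
    keep = np.sort(np.array(list(first.values()), dtype=int))
    return matrix.take_loci(keep)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts: the heterozygote count
    follows a known distribution under random mating, and the p-value
    sums the probabilities of all configurations no more probable than
    the observed one.  Monomorphic samples return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise InvalidParameterError("genotype counts must be non-negative "
                                    "with a positive total")
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    rare = min(n_A, n_a)
    from math import lgamma

    def logprob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (het * np.log(2.0)
                + lgamma(n + 1) - lgamma(hom_rare + 1) - lgamma(het + 1)
                - lgamma(hom_common + 1)
                + lgamma(n_A + 1) + lgamma(n_a + 1) - lgamma(2 * n + 1))

    hets = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([logprob(int(h)) for h in hets])
    logps -= logps.max()
    probs = np.exp(logps)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_pvalues(matrix: GenotypeMatrix) -> np.ndarray:
    """Exact-test p-value at each locus, over called genotypes."""
    d = matrix.dosages
    out = np.empty(matrix.n_loci)
    for j in range(matrix.n_loci):
        col = d[:, j]
        n_AA = int((col == 0).sum())
        n_Aa = int((col == 1).sum())
        n_aa = int((col == 2).sum())
        out[j] = hwe_exact_test(n_AA, n_Aa, n_aa) if n_AA + n_Aa + n_aa else 1.0
    return out


# ---------------------------------------------------------------------------
# PCA and FST

def impute_mean(matrix: GenotypeMatrix) -> np.ndarray:
    """Dosages as float with missing entries replaced by the locus mean."""
    d = matrix.dosages.astype(float)
    d[matrix.missing_mask] = np.nan
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


def pca_genotypes(matrix: GenotypeMatrix
                  ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix.

    Missing dosages are interpolated with the locus mean allele
    frequency; columns are centered (not scaled) and decomposed by SVD.

    Returns
    -------
    scores : (n_individuals, n_axes) principal-component scores
    explained : proportion of variance per axis (sums to 1)
    """
    if matrix.n_individuals < 2 or matrix.n_loci < 2:
        raise InvalidParameterError("PCA needs >= 2 individuals and loci")
    X = impute_mean(matrix)
    X -= X.mean(axis=0)
    if not np.any(X):
        raise InvalidParameterError("genotype matrix has zero variance")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    explained = S ** 2 / np.sum(S ** 2)
    return scores, explained


def wc_fst(matrix: GenotypeMatrix, labels) -> float:
    """Weir & Cockerham's theta across loci for two or more groups.

    Per-locus variance components a (among populations), b (among
    individuals within populations) and c (within individuals) are
    computed from allele frequencies and observed heterozygosities and
    combined as a ratio of sums across loci.  Loci monomorphic overall,
    or with a group entirely missing, are excluded.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_individuals:
        raise InvalidParameterError("labels must match individual count")
    groups = np.unique(labels)
    r = len(groups)
    if r < 2:
        raise InvalidParameterError("need >= 2 groups")
    d = matrix.dosages
    called = d != MISSING
    for g in groups:
        if not called[labels == g].any():
            raise EmptyResultError(f"group {g!r} has no called genotypes")
    num = 0.0
    den = 0.0
    for j in range(matrix.n_loci):
        col = d[:, j]
        ok = col != MISSING
        n_i, p_i, h_i = [], [], []
        valid = True
        for g in groups:
            sel = ok & (labels == g)
            n = int(sel.sum())
            if n == 0:
                valid = False
                break
            n_i.append(n)
            p_i.append(col[sel].sum() / (2.0 * n))
            h_i.append((col[sel] == 1).mean())
        if not valid:
            continue
        n_i = np.array(n_i, float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        pbar = np.sum(n_i * p_i) / (r * nbar)
        if pbar <= 0.0 or pbar >= 1.0:
            continue        # monomorphic overall
        nc = (r * nbar - np.sum(n_i ** 2) / (r * nbar)) / (r - 1)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        num += a
        den += a + b + c
    if den == 0.0:
        raise EmptyResultError("no polymorphic loci usable for FST")
    return float(num / den)
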
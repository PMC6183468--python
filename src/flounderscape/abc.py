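"""Dispersal estimation by rejection ABC on the joint site frequency
spectrum.

The observed SNP panel is reduced to the folded joint SFS of the two
demes (minor-allele copy counts per deme, pooled-sample folding), MAF-
matched to the ascertainment of the observed data, and projected onto
PCA axes fitted to a pilot batch of simulations.  Parameter draws from
the prior are ranked by Euclidean distance between simulated and
observed summaries and the closest fraction is retained; posterior
modes come from a Gaussian KDE on the accepted draws (deme sizes on the
log10 scale) and credible intervals are equal-tailed quantiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalescent import DemographicParams, PriorSpec, simulate_snp_panel
from .errors import EmptyResultError, InvalidParameterError
from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["JointSFS", "SummaryProjection", "ABCPosterior", "joint_sfs",
           "fold_panel", "sfs_maf_filter", "downsample_sfs",
           "structural_cell_mask", "fit_summary_projection", "project",
           "abc_reject", "run_abc"]


# ---------------------------------------------------------------------------
# joint SFS

@dataclass
class JointSFS:
    """Grid of locus counts by minor-allele copy number in two demes.

    ``counts[i, j]`` is the number of loci with ``i`` copies of the
    pooled-sample minor allele among the ``2*n1`` genes sampled in deme
    1 and ``j`` copies among the ``2*n2`` genes of deme 2.
    """

    counts: np.ndarray
    n1: int
    n2: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        expected = (2 * self.n1 + 1, 2 * self.n2 + 1)
        if self.counts.shape != expected:
            raise InvalidParameterError(
                f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise InvalidParameterError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def pooled_maf_grid(self) -> np.ndarray:
        """Pooled minor-allele frequency of each cell (folded)."""
        i = np.arange(2 * self.n1 + 1)[:, None]
        j = np.arange(2 * self.n2 + 1)[None, :]
        f = (i + j) / (2.0 * self.n1 + 2.0 * self.n2)
        return np.minimum(f, 1.0 - f)


def joint_sfs(matrix: GenotypeMatrix, deme_labels) -> JointSFS:
    """Fold the genotype matrix into the two-deme joint SFS.

    Loci with any missing genotype are excluded (count logged).  The
    minor allele at each locus is defined from the pooled sample; exact
    50/50 ties fold to the alternate allele.  Loci monomorphic in the
    sample land in cell (0, 0).
    """
    labels = np.asarray(deme_labels)
    if labels.shape[0] != matrix.n_individuals:
        raise InvalidParameterError("deme labels must match individuals")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise InvalidParameterError(f"need exactly 2 demes, got {list(uniq)}")
    sel1 = labels == uniq[0]
    sel2 = labels == uniq[1]
    if sel1.sum() == 0 or sel2.sum() == 0:
        raise EmptyResultError("a deme has no individuals")
    complete = ~(matrix.dosages == MISSING).any(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("joint SFS: dropped %d loci with missing genotypes",
                    n_dropped)
    d = matrix.dosages[:, complete]
    n1, n2 = int(sel1.sum()), int(sel2.sum())
    alt1 = d[sel1].sum(axis=0)
    alt2 = d[sel2].sum(axis=0)
    tot = 2 * (n1 + n2)
    alt = alt1 + alt2
    # fold to the pooled minor allele; ties stay with the alternate allele
    flip = alt > tot - alt
    i = np.where(flip, 2 * n1 - alt1, alt1)
    j = np.where(flip, 2 * n2 - alt2, alt2)
    counts = np.zeros((2 * n1 + 1, 2 * n2 + 1), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    return JointSFS(counts, n1, n2)


def fold_panel(G: np.ndarray, n1: int, n2: int) -> JointSFS:
    """Joint SFS straight from a complete-data dosage array.

    Equivalent to :func:`joint_sfs` on a matrix whose first ``n1`` rows
    are deme 1, without container overhead; used in the hot simulation
    loop of :func:`run_abc`.
    """
    alt1 = G[:n1].sum(axis=0, dtype=np.int64)
    alt2 = G[n1:].sum(axis=0, dtype=np.int64)
    tot = 2 * (n1 + n2)
    alt = alt1 + alt2
    flip = alt > tot - alt
    i = np.where(flip, 2 * n1 - alt1, alt1)
    j = np.where(flip, 2 * n2 - alt2, alt2)
    counts = np.zeros((2 * n1 + 1, 2 * n2 + 1), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    return JointSFS(counts, n1, n2)


def sfs_maf_filter(sfs: JointSFS, cutoff: float) -> tuple[JointSFS, int]:
    """Zero cells whose pooled minor-allele frequency is below ``cutoff``.

    Returns the filtered spectrum and the number of loci removed.
    """
    keep = sfs.pooled_maf_grid() >= cutoff
    counts = np.where(keep, sfs.counts, 0)
    removed = int(sfs.total - counts.sum())
    return JointSFS(counts, sfs.n1, sfs.n2), removed


def downsample_sfs(sfs: JointSFS, target: int,
                   rng: np.random.Generator) -> JointSFS:
    """Draw ``target`` loci without replacement, proportional to counts
    (multivariate hypergeometric)."""
    if target < 0:
        raise InvalidParameterError("target must be >= 0")
    if sfs.total < target:
        raise InvalidParameterError(
            f"cannot downsample {sfs.total} loci to {target}")
    flat = sfs.counts.ravel()
    drawn = rng.multivariate_hypergeometric(flat.astype(np.int64), target)
    return JointSFS(drawn.reshape(sfs.counts.shape), sfs.n1, sfs.n2)


# ---------------------------------------------------------------------------
# PCA summaries

@dataclass
class SummaryProjection:
    """PCA basis fitted on a pilot batch of SFS summary vectors.

    ``cell_mask`` selects the grid cells that survive the structural MAF
    filter (the summary vector length); ``mean`` centres pilot vectors;
    rows of ``components`` are orthonormal directions.
    """

    mean: np.ndarray
    components: np.ndarray
    cell_mask: np.ndarray
    explained_variance: np.ndarray = field(default=None)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _sfs_vector(sfs: JointSFS, cell_mask: np.ndarray) -> np.ndarray:
    return sfs.counts.ravel()[cell_mask].astype(float)


def structural_cell_mask(n1: int, n2: int, maf_cutoff: float) -> np.ndarray:
    """Flat mask of grid cells retained by the MAF filter (row-major)."""
    grid = JointSFS(np.zeros((2 * n1 + 1, 2 * n2 + 1), np.int64), n1, n2)
    return (grid.pooled_maf_grid() >= maf_cutoff).ravel()


def fit_summary_projection(pilot: list[JointSFS],
                           retain: int | None = None,
                           maf_cutoff: float = 0.0) -> SummaryProjection:
    """Fit PCA axes to a pilot batch of joint spectra.

    Grids are flattened row-major, restricted to cells passing the
    structural MAF mask, centred by the pilot mean and decomposed by
    SVD.  ``retain`` beyond the pilot rank is truncated with a warning;
    by default all available components are kept.
    """
    if len(pilot) < 2:
        raise InvalidParameterError("pilot batch must have >= 2 spectra")
    n1, n2 = pilot[0].n1, pilot[0].n2
    mask = structural_cell_mask(n1, n2, maf_cutoff)
    X = np.array([_sfs_vector(s, mask) for s in pilot])
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if retain is None:
        retain = rank
    if retain > rank:
        logger.warning("retain=%d exceeds pilot rank %d; truncating",
                       retain, rank)
        retain = rank
    var = S ** 2 / max(len(pilot) - 1, 1)
    return SummaryProjection(mean=mean, components=Vt[:retain],
                             cell_mask=mask,
                             explained_variance=var[:retain])


def project(sfs: JointSFS, projection: SummaryProjection) -> np.ndarray:
    """Project a spectrum onto the fitted PCA axes."""
    v = _sfs_vector(sfs, projection.cell_mask) - projection.mean
    return projection.components @ v


# ---------------------------------------------------------------------------
# rejection sampling

@dataclass
class ABCPosterior:
    """Accepted draws plus per-parameter modes and credible intervals."""

    draws: pd.DataFrame                 # sim_id, pop_one, pop_two, dispersal,
                                        # distance, accepted
    accepted: pd.DataFrame
    modes: dict
    ci95: dict
    distance_threshold: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in ("pop_one", "pop_two", "dispersal"):
            lo, hi = self.ci95[p]
            rows.append((p, self.modes[p], lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "mode", "ci_lo",
                                           "ci_hi"])


def _kde_mode(values: np.ndarray, log10_scale: bool) -> float:
    x = np.log10(values) if log10_scale else values
    if np.ptp(x) == 0:
        return float(values[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    mode = grid[int(np.argmax(kde(grid)))]
    return float(10 ** mode if log10_scale else mode)


def abc_reject(summaries: np.ndarray, params: list[DemographicParams],
               observed: np.ndarray, accept_frac: float) -> ABCPosterior:
    """Simple rejection: keep the closest fraction of simulations.

    Distances are Euclidean in summary space; the accepted count is
    ``round(accept_frac * n)`` with ties at the boundary broken by
    simulation index.  Modes are Gaussian-KDE maxima over the accepted
    draws (deme sizes on the log10 scale); the 95% credible interval is
    the equal-tailed quantile pair.
    """
    summaries = np.asarray(summaries, float)
    if len(summaries) != len(params):
        raise InvalidParameterError("summaries and params length mismatch")
    if not 0.0 < accept_frac <= 1.0:
        raise InvalidParameterError("accept_frac must lie in (0, 1]")
    n = len(params)
    n_accept = int(round(accept_frac * n))
    if n_accept == 0:
        raise InvalidParameterError(
            f"accept_frac={accept_frac} accepts zero of {n} simulations")
    dist = np.sqrt(((summaries - observed[None, :]) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")
    accepted_idx = np.sort(order[:n_accept])
    accepted_mask = np.zeros(n, bool)
    accepted_mask[accepted_idx] = True
    draws = pd.DataFrame({
        "sim_id": np.arange(n),
        "pop_one": [p.pop_one_size for p in params],
        "pop_two": [p.pop_two_size for p in params],
        "dispersal": [p.dispersal for p in params],
        "distance": dist,
        "accepted": accepted_mask,
    })
    acc = draws[draws["accepted"]].reset_index(drop=True)
    modes, ci95 = {}, {}
    for name, logscale in (("pop_one", True), ("pop_two", True),
                           ("dispersal", False)):
        vals = acc[name].to_numpy()
        modes[name] = _kde_mode(vals, logscale)
        ci95[name] = (float(np.quantile(vals, 0.025)),
                      float(np.quantile(vals, 0.975)))
    return ABCPosterior(draws=draws, accepted=acc, modes=modes, ci95=ci95,
                        distance_threshold=float(dist[order[n_accept - 1]]))


# ---------------------------------------------------------------------------
# end-to-end

def run_abc(observed: GenotypeMatrix, deme_labels,
            prior: PriorSpec = PriorSpec(),
            n_sims: int = 100_000,
            pilot_size: int = 10_000,
            accept_frac: float = 0.005,
            seed: int = 0,
            maf_cutoff: float | None = None,
            retain_components: int | None = None,
            observed_sfs: JointSFS | None = None) -> ABCPosterior:
    """Estimate deme sizes and dispersal from an observed SNP panel.

    Steps: fold the observed complete-data loci into the joint SFS;
    draw parameters from the prior; simulate a matching panel for each
    draw at the observed per-deme sample sizes with MAF-matched
    ascertainment; fit PCA axes to the first ``pilot_size`` simulated
    spectra and project everything onto them; rejection-accept the
    closest ``accept_frac``.  ``maf_cutoff=None`` infers the observed
    ascertainment cutoff as the smallest pooled minor-allele frequency
    present in the observed spectrum.

    The simulator re-simulates each locus until the target count is
    reached, so simulated spectra already hold exactly the observed
    locus count and the downsampling step is the identity.
    """
    rng = np.random.default_rng(seed)
    if observed_sfs is None:
        observed_sfs = joint_sfs(observed, deme_labels)
    n1, n2 = observed_sfs.n1, observed_sfs.n2
    if maf_cutoff is None:
        maf = observed_sfs.pooled_maf_grid()
        nonzero = observed_sfs.counts > 0
        polymorphic = nonzero & (maf > 0)
        maf_cutoff = float(maf[polymorphic].min()) if polymorphic.any() else 0.0
    obs_filtered, _ = sfs_maf_filter(observed_sfs, maf_cutoff)
    n_target = obs_filtered.total
    if n_target == 0:
        raise EmptyResultError("no observed loci survive the MAF cutoff")
    if pilot_size < 2 or pilot_size > n_sims:
        raise InvalidParameterError("need 2 <= pilot_size <= n_sims")
    logger.info("ABC: %d observed loci, MAF cutoff %.4f, %d sims",
                n_target, maf_cutoff, n_sims)
    params = PriorSpec.sample(prior, rng, n_sims)
    spectra = []
    for p in params:
        G = simulate_snp_panel((n1, n2), p, n_target, maf_cutoff, rng)
        sim_sfs = fold_panel(G, n1, n2)
        sim_sfs, _ = sfs_maf_filter(sim_sfs, maf_cutoff)
        if sim_sfs.total > n_target:
            sim_sfs = downsample_sfs(sim_sfs, n_target, rng)
        spectra.append(sim_sfs)
    projection = fit_summary_projection(spectra[:pilot_size],
                                        retain=retain_components,
                                        maf_cutoff=maf_cutoff)
    summaries = np.array([project(s, projection) for s in spectra])
    observed_summary = project(obs_filtered, projection)
    return abc_reject(summaries, params, observed_summary, accept_frac)
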
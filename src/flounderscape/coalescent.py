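"""Two-deme structured-coalescent simulator.

This is the generative engine behind both the synthetic study datasets and
the ABC reference table: a continuous-time structured coalescent for two
demes of diploid effective sizes ``pop_one_size`` and ``pop_two_size``
connected by symmetric migration at per-lineage rate ``dispersal`` (the
per-generation probability that an individual disperses to the other
deme, viewed backward in time).  Each unlinked locus is an independent
genealogy carrying a single mutation placed uniformly along its total
branch length, which models a panel of unlinked bi-allelic SNPs, one per
sequenced contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import (InvalidParameterError, NoCoalescenceError,
                     SimulationFailureError)

__all__ = [
    "DemographicParams",
    "PriorSpec",
    "Genealogy",
    "simulate_genealogy",
    "simulate_snp_panel",
    "DEFAULT_MAX_TIME",
]

#: Default cap on coalescent time, in generations.  Far above any
#: time-to-MRCA reachable under the supported effective sizes; hitting it
#: indicates effectively isolated lineages.
DEFAULT_MAX_TIME = 1e9


@dataclass(frozen=True)
class DemographicParams:
    """Parameters of the two-deme dispersal model.

    Attributes
    ----------
    pop_one_size, pop_two_size
        Diploid effective sizes of the northern and southern deme.
    dispersal
        Per-generation probability that an individual disperses to the
        other deme, in [0, 0.5]; applied symmetrically.
    """

    pop_one_size: float
    pop_two_size: float
    dispersal: float

    def __post_init__(self):
        if self.pop_one_size < 2 or self.pop_two_size < 2:
            raise InvalidParameterError(
                f"deme sizes must be >= 2 (got {self.pop_one_size}, "
                f"{self.pop_two_size})")
        if not 0.0 <= self.dispersal <= 0.5:
            raise InvalidParameterError(
                f"dispersal must lie in [0, 0.5] (got {self.dispersal})")


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the ABC analysis.

    Deme sizes are log-uniform between ``size_lo`` and ``size_hi``;
    dispersal is uniform between ``disp_lo`` and ``disp_hi``.
    """

    size_lo: float = 100.0
    size_hi: float = 100_000.0
    disp_lo: float = 0.0
    disp_hi: float = 0.5

    def __post_init__(self):
        if self.size_lo <= 0 or self.size_lo >= self.size_hi:
            raise InvalidParameterError("size prior bounds must satisfy "
                                        "0 < lo < hi")
        if not (0 <= self.disp_lo < self.disp_hi <= 0.5):
            raise InvalidParameterError("dispersal prior bounds must satisfy "
                                        "0 <= lo < hi <= 0.5")

    def sample(self, rng: np.random.Generator, n: int) -> list[DemographicParams]:
        """Draw ``n`` independent parameter sets from the prior."""
        lo, hi = np.log10(self.size_lo), np.log10(self.size_hi)
        n1 = 10.0 ** rng.uniform(lo, hi, n)
        n2 = 10.0 ** rng.uniform(lo, hi, n)
        d = rng.uniform(self.disp_lo, self.disp_hi, n)
        return [DemographicParams(a, b, c) for a, b, c in zip(n1, n2, d)]


@dataclass
class Genealogy:
    """A realized coalescent tree over sampled gene copies.

    Nodes ``0..n_leaves-1`` are the sampled lineages (leaves, time 0);
    internal nodes follow in coalescence order, the last being the root.
    ``leaf_demes`` records the deme each sampled lineage started in.
    """

    parent: np.ndarray
    left_child: np.ndarray
    right_child: np.ndarray
    time: np.ndarray
    leaf_demes: np.ndarray
    n_leaves: int = field(init=False)

    def __post_init__(self):
        self.n_leaves = len(self.leaf_demes)

    @property
    def root(self) -> int:
        return len(self.time) - 1

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths, in generations."""
        if self.n_leaves < 2:
            return 0.0
        p = self.parent[:-1]
        return float(np.sum(self.time[p] - self.time[:-1]))

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf ids in the subtree rooted at ``node``."""
        stack = [node]
        out = []
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.append(int(self.left_child[v]))
                stack.append(int(self.right_child[v]))
        return np.array(sorted(out), dtype=np.int64)


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogy(k1: int, k2: int, params: DemographicParams,
                       rng: np.random.Generator,
                       max_time: float = DEFAULT_MAX_TIME) -> Genealogy:
    """Simulate one structured-coalescent genealogy.

    Parameters
    ----------
    k1, k2
        Numbers of sampled lineages (gene copies) starting in each deme.
    params
        Demographic model.
    rng
        Source of randomness.
    max_time
        Raise :class:`NoCoalescenceError` if the most recent common
        ancestor is not reached by this many generations.
    """
    if k1 < 0 or k2 < 0 or k1 + k2 < 1:
        raise InvalidParameterError("need at least one sampled lineage")
    leaf_demes = np.concatenate([np.ones(k1, np.int8),
                                 np.full(k2, 2, np.int8)])
    if k1 + k2 == 1:
        one = np.array([-1], np.int32)
        return Genealogy(parent=one.copy(), left_child=one.copy(),
                         right_child=one.copy(),
                         time=np.zeros(1), leaf_demes=leaf_demes)
    parent, lch, rch, ntime, status = _kernels.sim_genealogy_kernel(
        _derive_seed(rng), k1, k2, params.pop_one_size, params.pop_two_size,
        params.dispersal, max_time)
    if status == _kernels.STATUS_NO_COALESCENCE:
        raise NoCoalescenceError(
            "total event rate reached zero: lineages isolated in separate "
            "demes with dispersal = 0 cannot coalesce")
    if status == _kernels.STATUS_MAX_TIME:
        raise NoCoalescenceError(
            f"no common ancestor reached within max_time={max_time:g} "
            "generations")
    return Genealogy(parent=parent, left_child=lch, right_child=rch,
                     time=ntime, leaf_demes=leaf_demes)


def simulate_snp_panel(sample_sizes: tuple[int, int],
                       params: DemographicParams,
                       n_loci: int,
                       maf_cutoff: float = 0.0,
                       rng: np.random.Generator | None = None,
                       max_time: float = DEFAULT_MAX_TIME,
                       attempt_factor: int = 1000) -> np.ndarray:
    """Simulate diploid genotypes at unlinked bi-allelic SNPs.

    Each locus is an independent genealogy of ``2*(n1+n2)`` gene copies
    with a single mutation; a sampled individual's genotype is the count
    of mutant copies among its two lineages.  Loci with sample minor
    allele frequency below ``maf_cutoff`` are rejected and re-simulated,
    with an attempt budget of ``attempt_factor * n_loci``.

    Returns
    -------
    numpy.ndarray
        ``(n1 + n2, n_loci)`` int8 matrix of alternate-allele dosages;
        rows ``0..n1-1`` are deme-1 individuals.
    """
    n1, n2 = sample_sizes
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise InvalidParameterError("need at least one sampled individual")
    if n_loci < 1:
        raise InvalidParameterError("n_loci must be >= 1")
    if not 0.0 <= maf_cutoff < 0.5:
        raise InvalidParameterError("maf_cutoff must lie in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng()
    max_attempts = attempt_factor * n_loci
    G, attempts, status = _kernels.sim_panel_kernel(
        _derive_seed(rng), n1, n2, params.pop_one_size, params.pop_two_size,
        params.dispersal, n_loci, maf_cutoff, max_time, max_attempts)
    if status == _kernels.STATUS_BUDGET:
        rate = (G.shape[1] and np.count_nonzero(G.any(axis=0))) / attempts
        raise SimulationFailureError(
            f"exhausted {max_attempts} simulation attempts before retaining "
            f"{n_loci} loci at maf_cutoff={maf_cutoff} "
            f"(acceptance rate ~{rate:.3g})", acceptance_rate=rate)
    if status in (_kernels.STATUS_NO_COALESCENCE, _kernels.STATUS_MAX_TIME):
        raise NoCoalescenceError(
            "a locus genealogy failed to coalesce; check dispersal and "
            "max_time")
    return G
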
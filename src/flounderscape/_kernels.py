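"""Numba kernels for the two-deme structured coalescent.

The simulator draws independent single-SNP genealogies under a model of
two demes of diploid effective sizes ``N1``/``N2`` exchanging migrants at
a per-lineage, per-generation rate ``m`` (the backward-in-time image of a
forward dispersal probability).  Within deme *i* each pair of lineages
coalesces at rate ``1/(4*Ni)`` per pair (time in generations, diploid
scaling); waiting times are exponential.  One mutation is placed uniformly
at random along the total branch length of each retained genealogy, which
yields exactly one bi-allelic segregating site per locus.

These loops are the computational bottleneck of the ABC stage (millions
of genealogies with migration-dominated event counts), hence numba.
Status codes returned by the kernels:

* 0  success
* 1  no coalescence possible (total event rate hit zero)
* 2  maximum time exceeded
* 3  attempt budget exhausted during MAF rejection
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NO_COALESCENCE = 1
STATUS_MAX_TIME = 2
STATUS_BUDGET = 3


@njit(cache=True)
def _sim_tree(k1, k2, N1, N2, m, max_time, parent, lchild, rchild, ntime,
              act1, act2, buf1, buf2):
    """Simulate one structured-coalescent tree in place.

    Leaves 0..k1-1 start in deme 1, leaves k1..k1+k2-1 in deme 2.
    Internal nodes are numbered k1+k2 .. 2*(k1+k2)-2; the last one is the
    root.  Returns a status code.

    Sampling is exact but avoids enumerating individual migration events
    (whose count grows like m * total branch length and dominates at
    large N*m).  Candidate coalescence times are proposed from a Poisson
    process at the configuration-independent bound
    ``lam_max = k(k-1)/4 * max(1/N1, 1/N2)``.  Between proposals each
    lineage's deme evolves as an independent symmetric two-state Markov
    chain with flip probability ``(1 - exp(-2 m dt)) / 2`` over a gap
    ``dt`` (migration is independent of coalescence, so the chains can
    be advanced lazily).  A proposal at a time with deme occupancies
    (a, b) is accepted with probability
    ``[a(a-1)/4N1 + b(b-1)/4N2] / lam_max``, which is <= 1 by
    construction; accepted proposals merge a uniform pair within a deme
    chosen proportionally to its rate.  This is the standard thinning
    construction for a doubly-stochastic Poisson process and samples the
    same law as event-by-event simulation.
    """
    k = k1 + k2
    for i in range(k1):
        act1[i] = i
        ntime[i] = 0.0
    for i in range(k2):
        act2[i] = k1 + i
        ntime[k1 + i] = 0.0
    n1a = k1
    n2a = k2
    nxt = k
    t = 0.0
    while n1a + n2a > 1:
        na = n1a + n2a
        if m <= 0.0 and n1a <= 1 and n2a <= 1:
            return STATUS_NO_COALESCENCE
        inv_small = 1.0 / N1 if N1 < N2 else 1.0 / N2
        lam_max = na * (na - 1) * 0.25 * inv_small
        # propose next candidate coalescence time
        dt = np.random.exponential(1.0 / lam_max)
        t += dt
        if t > max_time:
            return STATUS_MAX_TIME
        # advance every lineage's deme over the gap: each flips
        # independently with probability pflip, realized as binomial
        # counts plus a uniformly chosen subset (partial Fisher-Yates)
        if m > 0.0:
            x = 2.0 * m * dt
            pflip = 0.5 if x > 40.0 else 0.5 * (1.0 - np.exp(-x))
            b1 = np.random.binomial(n1a, pflip) if n1a > 0 else 0
            b2 = np.random.binomial(n2a, pflip) if n2a > 0 else 0
            for q in range(b1):
                idx = int(np.random.random() * (n1a - q))
                v = act1[idx]
                act1[idx] = act1[n1a - 1 - q]
                act1[n1a - 1 - q] = v
            for q in range(b2):
                idx = int(np.random.random() * (n2a - q))
                v = act2[idx]
                act2[idx] = act2[n2a - 1 - q]
                act2[n2a - 1 - q] = v
            for q in range(b2):
                buf1[q] = act2[n2a - b2 + q]
            n2a -= b2
            for q in range(b1):
                act2[n2a + q] = act1[n1a - b1 + q]
            n2a += b1
            n1a -= b1
            for q in range(b2):
                act1[n1a + q] = buf1[q]
            n1a += b2
        cr1 = n1a * (n1a - 1) / (4.0 * N1)
        cr2 = n2a * (n2a - 1) / (4.0 * N2)
        if np.random.random() * lam_max >= cr1 + cr2:
            continue            # thinned (rejected) proposal
        if np.random.random() * (cr1 + cr2) < cr1:
            i = int(np.random.random() * n1a)
            j = int(np.random.random() * (n1a - 1))
            if j >= i:
                j += 1
            a = act1[i]
            b = act1[j]
            parent[a] = nxt
            parent[b] = nxt
            lchild[nxt] = a
            rchild[nxt] = b
            ntime[nxt] = t
            act1[i] = nxt
            act1[j] = act1[n1a - 1]
            n1a -= 1
            nxt += 1
        else:
            i = int(np.random.random() * n2a)
            j = int(np.random.random() * (n2a - 1))
            if j >= i:
                j += 1
            a = act2[i]
            b = act2[j]
            parent[a] = nxt
            parent[b] = nxt
            lchild[nxt] = a
            rchild[nxt] = b
            ntime[nxt] = t
            act2[i] = nxt
            act2[j] = act2[n2a - 1]
            n2a -= 1
            nxt += 1
    return STATUS_OK


@njit(cache=True)
def sim_genealogy_kernel(seed, k1, k2, N1, N2, m, max_time):
    """Draw one genealogy; return (parent, lchild, rchild, ntime, status)."""
    np.random.seed(seed)
    k = k1 + k2
    nn = 2 * k - 1
    parent = np.full(nn, -1, np.int32)
    lchild = np.full(nn, -1, np.int32)
    rchild = np.full(nn, -1, np.int32)
    ntime = np.zeros(nn, np.float64)
    act1 = np.empty(k, np.int32)
    act2 = np.empty(k, np.int32)
    buf1 = np.empty(k, np.int32)
    buf2 = np.empty(k, np.int32)
    status = _sim_tree(k1, k2, N1, N2, m, max_time, parent, lchild, rchild,
                       ntime, act1, act2, buf1, buf2)
    return parent, lchild, rchild, ntime, status


@njit(cache=True)
def sim_panel_kernel(seed, n1, n2, N1, N2, m, n_loci, maf_cutoff, max_time,
                     max_attempts):
    """Simulate an unlinked SNP panel of diploid genotypes.

    One independent genealogy and one mutation per retained locus; loci
    whose sample minor-allele frequency falls below ``maf_cutoff`` are
    rejected and re-simulated.  Leaves 2i and 2i+1 are the two gene
    copies of diploid individual i; the first ``n1`` individuals belong
    to deme 1.

    Returns (G, attempts, status) with G an (n1+n2, n_loci) int8 matrix
    of alternate-allele dosages (the mutation defines the alternate
    allele).
    """
    np.random.seed(seed)
    nind = n1 + n2
    k = 2 * nind
    G = np.zeros((nind, n_loci), np.int8)
    nn = 2 * k - 1
    parent = np.full(nn, -1, np.int32)
    lchild = np.full(nn, -1, np.int32)
    rchild = np.full(nn, -1, np.int32)
    ntime = np.zeros(nn, np.float64)
    act1 = np.empty(k, np.int32)
    act2 = np.empty(k, np.int32)
    buf1 = np.empty(k, np.int32)
    buf2 = np.empty(k, np.int32)
    stack = np.empty(k, np.int32)
    carriers = np.empty(k, np.int32)
    attempts = 0
    loc = 0
    while loc < n_loci:
        if attempts >= max_attempts:
            return G, attempts, STATUS_BUDGET
        attempts += 1
        status = _sim_tree(2 * n1, 2 * n2, N1, N2, m, max_time, parent,
                           lchild, rchild, ntime, act1, act2, buf1, buf2)
        if status != STATUS_OK:
            return G, attempts, status
        # total branch length over all non-root edges
        total = 0.0
        for v in range(nn - 1):
            total += ntime[parent[v]] - ntime[v]
        u = np.random.random() * total
        edge = nn - 2
        acc = 0.0
        for v in range(nn - 1):
            acc += ntime[parent[v]] - ntime[v]
            if u < acc:
                edge = v
                break
        # leaves below the mutated edge carry the alternate allele
        ncar = 0
        sp = 0
        stack[sp] = edge
        sp += 1
        while sp > 0:
            sp -= 1
            v = stack[sp]
            if v < k:
                carriers[ncar] = v
                ncar += 1
            else:
                stack[sp] = lchild[v]
                sp += 1
                stack[sp] = rchild[v]
                sp += 1
        minor = ncar if ncar <= k - ncar else k - ncar
        if minor / k < maf_cutoff:
            continue
        for i in range(ncar):
            G[carriers[i] // 2, loc] += 1
        loc += 1
    return G, attempts, STATUS_OK
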
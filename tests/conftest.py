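"""Shared fixtures: small genotype matrices and a rule-by-rule designed
filtering panel."""

import numpy as np
import pandas as pd
import pytest

from flounderscape.genotypes import (MISSING, GenotypeMatrix, VariantRecord)

N_IND = 40


def make_matrix(dosages, contigs=None, positions=None, ids=None,
                **sample_cols) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    loci = pd.DataFrame({
        "contig": contigs if contigs is not None
        else [f"c{j}" for j in range(L)],
        "position": positions if positions is not None
        else np.arange(1, L + 1),
    })
    samples = pd.DataFrame({"id": ids if ids is not None
                            else [f"s{i}" for i in range(n)],
                            **sample_cols})
    return GenotypeMatrix(dosages, loci, samples)


def _dosage_col(n, n_het, n_homalt=0, n_missing=0):
    col = np.zeros(n, dtype=np.int8)
    col[:n_het] = 1
    col[n_het:n_het + n_homalt] = 2
    if n_missing:
        col[-n_missing:] = MISSING
    return col


@pytest.fixture(scope="session")
def designed_filter_panel():
    """20 records over 40 individuals, one designed to fail each rule.

    Returns (matrix, records, expectations) where expectations maps each
    enabled rule name to the list of contigs it must remove.
    """
    n = N_IND
    cols = []
    recs = []
    expect = {}

    def add(contig, dos, depth=30.0, qual=None, ab=0.5, mqm=40.0, mqmr=40.0,
            depths=None):
        if depths is None:
            depths = np.full(n, float(depth))
        if qual is None:
            qual = float(2.0 / 3.0 * np.nansum(depths))
        cols.append(dos)
        recs.append(VariantRecord(contig=contig, position=len(recs) + 1,
                                  qual=float(qual), depths=depths,
                                  allele_balance=ab, mqm=mqm, mqmr=mqmr))

    # nine clean records (8/40 hets, depth 30, qual ratio 0.67)
    for i in range(9):
        add(f"good{i}", _dosage_col(n, 8))
    # MAF exactly at the 0.05 boundary: 4 alt copies of 80 -> retained
    add("maf_boundary", _dosage_col(n, 4))

    # one victim per rule, passing all earlier rules
    add("v_callrate_init", _dosage_col(n, 4, n_missing=24))
    expect["call_rate_initial"] = ["v_callrate_init"]
    add("v_mac", _dosage_col(n, 2))
    expect["minor_allele_count"] = ["v_mac"]
    # four genotypes on 2 reads get recoded missing -> call rate 0.9
    low = np.full(n, 30.0)
    low[:4] = 2.0
    add("v_callrate95", _dosage_col(n, 8), depths=low)
    expect["call_rate"] = ["v_callrate95"]
    add("v_maf", _dosage_col(n, 3))
    expect["maf"] = ["v_maf"]
    add("v_meandepth", _dosage_col(n, 8), depth=10.0, qual=300.0)
    expect["mean_depth_min"] = ["v_meandepth"]
    add("v_ab", _dosage_col(n, 8), ab=0.20)
    expect["allele_balance"] = ["v_ab"]
    add("v_qd", _dosage_col(n, 8), qual=100.0)      # 100/1200 < 0.2
    expect["qual_depth_ratio"] = ["v_qd"]
    add("v_mq", _dosage_col(n, 8), mqm=80.0, mqmr=40.0)
    expect["mapq_ratio"] = ["v_mq"]
    # total depth 3600 beyond mean+SD of (10x1200, 3600, 2400), weak qual
    add("v_highdepth", _dosage_col(n, 8), depth=90.0, qual=2400.0)
    expect["high_depth_qual"] = ["v_highdepth"]
    # mean depth 60 above the 95% quantile of (10x30, 60); strong qual
    # (5000 >= 2 x 2400) so it survives the high-depth rule
    add("v_quantile", _dosage_col(n, 8), depth=60.0, qual=5000.0)
    expect["mean_depth_quantile"] = ["v_quantile"]

    dosages = np.column_stack(cols)
    matrix = make_matrix(dosages,
                         contigs=[r.contig for r in recs],
                         positions=[r.position for r in recs])
    return matrix, recs, expect


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic 10-individual, 50-locus coalescent panel."""
    from flounderscape.coalescent import DemographicParams, simulate_snp_panel
    rng = np.random.default_rng(42)
    G = simulate_snp_panel((5, 5), DemographicParams(1000, 1000, 0.2), 50,
                           rng=rng)
    return make_matrix(G)
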
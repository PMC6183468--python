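"""End-to-end orchestration: simulate -> filter -> structure -> IBD ->
ABC -> environment scan, with one config, one seed and a manifest.

Every stage writes plain-text outputs under ``out_dir`` and records a
SHA-256 hash of each file in the run manifest, so a rerun with the same
config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from . import envscan, ibd
from .coalescent import PriorSpec
from .errors import FlounderscapeError
from .genotypes import (FilterConfig, filter_variants, hwe_pvalues,
                        one_snp_per_contig, pca_genotypes, read_vcf, wc_fst,
                        write_vcf)
from .study import SimStudyConfig, simulate_study

logger = logging.getLogger(__name__)

#: Synthetic-coast analogues of the four grouping breaks (latitudes,
#: south to north: Cape Fear, Cape Hatteras, Hudson Canyon, Atlantis
#: Canyon counterparts).
DEFAULT_GROUP_BREAKS = (33.9, 35.25, 38.0, 40.1)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full synthetic rerun."""

    out_dir: str = "runs/demo"
    seed: int = 0
    # stage toggles
    do_filter: bool = True
    do_structure: bool = True
    do_ibd: bool = True
    do_abc: bool = True
    do_scan: bool = True
    # inputs: either a simulated study (default) or user files
    vcf: str | None = None
    meta: str | None = None
    study: SimStudyConfig = field(default_factory=SimStudyConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    # IBD
    ibd_permutations: int = 10_000
    # ABC (scaled-down defaults; the survey-scale run used 100,000
    # simulations with a 10,000-simulation pilot and 0.5% acceptance)
    prior: PriorSpec = field(default_factory=PriorSpec)
    abc_sims: int = 5_000
    abc_pilot: int = 1_000
    abc_accept: float = 0.01
    north_south_break: float = 35.25
    # scan
    group_breaks: tuple = DEFAULT_GROUP_BREAKS
    bf_threshold: float = 3.0
    bf_permutations: int = 10
    rda_permutations: int = 500

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("study", SimStudyConfig), ("filters", FilterConfig),
                         ("prior", PriorSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "group_breaks" in raw:
            raw["group_breaks"] = tuple(raw["group_breaks"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    rng = np.random.default_rng(config.seed)

    def record(stage: str, paths: dict, started: float, **info):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - started, 2), **info}
        for name, p in paths.items():
            manifest["outputs"][f"{stage}/{name}"] = {
                "path": str(p), "sha256": _sha256(Path(p))}

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"error": str(exc)}
        _write_manifest(out, manifest)
        raise FlounderscapeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- inputs ---------------------------------------------------------
    t0 = time.time()
    try:
        if config.vcf is not None:
            matrix, records = read_vcf(config.vcf)
            meta = pd.read_csv(config.meta, sep="\t")
            matrix.samples = meta.iloc[:len(matrix.samples)].reset_index(drop=True)
            env = meta
            record("input", {}, t0, vcf=config.vcf)
        else:
            study = SimStudyConfig(**{**asdict(config.study),
                                      "seed": config.seed})
            data = simulate_study(study)
            matrix, records, env = data.matrix, data.records, data.env
            paths = data.write(str(out / "study"))
            record("simulate", paths, t0, n_loci=matrix.n_loci,
                   n_individuals=matrix.n_individuals)
    except FlounderscapeError:
        raise
    except Exception as exc:
        fail("input", exc)

    # ---- filtering ------------------------------------------------------
    if config.do_filter:
        t0 = time.time()
        try:
            matrix, audit = filter_variants(matrix, records, config.filters)
            matrix = one_snp_per_contig(matrix)
            audit.log.to_csv(out / "filter_audit.tsv", sep="\t", index=False)
            write_vcf(matrix, None, str(out / "filtered.vcf"))
            env = env[env["id"].isin(matrix.samples["id"])].reset_index(drop=True)
            record("filter", {"audit": out / "filter_audit.tsv",
                              "vcf": out / "filtered.vcf"}, t0,
                   remaining_loci=matrix.n_loci,
                   mean_depth_cutoff=float(audit.realized_mean_depth_cutoff))
        except Exception as exc:
            fail("filter", exc)

    lat = matrix.samples["lat"].to_numpy(float)
    deme = np.where(lat >= config.north_south_break, "north", "south")

    # ---- structure: PCA + FST ------------------------------------------
    if config.do_structure:
        t0 = time.time()
        try:
            scores, explained = pca_genotypes(matrix)
            pca_df = matrix.samples[["id", "lat", "lon"]].copy()
            pca_df["pc1"], pca_df["pc2"] = scores[:, 0], scores[:, 1]
            pca_df.to_csv(out / "pca.tsv", sep="\t", index=False)
            fst = wc_fst(matrix, deme)
            record("structure", {"pca": out / "pca.tsv"}, t0,
                   fst=float(fst),
                   pc1_pct=float(100 * explained[0]),
                   pc2_pct=float(100 * explained[1]))
        except Exception as exc:
            fail("structure", exc)

    # ---- isolation by distance -----------------------------------------
    if config.do_ibd:
        t0 = time.time()
        try:
            d_gen = ibd.rousset_distance(matrix)
            lon = matrix.samples["lon"].to_numpy(float)
            d_geo = ibd.great_circle_matrix(lat, lon, d_gen.ids)
            r, p = ibd.mantel_test(d_gen, d_geo, config.ibd_permutations, rng)
            pd.DataFrame(d_gen.values, index=d_gen.ids,
                         columns=d_gen.ids).to_csv(out / "rousset.tsv",
                                                   sep="\t")
            record("ibd", {"rousset": out / "rousset.tsv"}, t0,
                   mantel_r=float(r), mantel_p=float(p),
                   permutations=config.ibd_permutations)
        except Exception as exc:
            fail("ibd", exc)

    # ---- ABC dispersal --------------------------------------------------
    if config.do_abc:
        t0 = time.time()
        try:
            post = abc_mod.run_abc(
                matrix, deme, config.prior, n_sims=config.abc_sims,
                pilot_size=config.abc_pilot, accept_frac=config.abc_accept,
                seed=int(rng.integers(1, 2**31 - 1)))
            post.draws.to_csv(out / "abc_draws.tsv", sep="\t", index=False)
            post.summary().to_csv(out / "abc_posterior.tsv", sep="\t",
                                  index=False)
            record("abc", {"draws": out / "abc_draws.tsv",
                           "posterior": out / "abc_posterior.tsv"}, t0,
                   **{f"{k}_mode": float(v) for k, v in post.modes.items()},
                   dispersal_ci=[float(x) for x in post.ci95["dispersal"]])
        except Exception as exc:
            fail("abc", exc)

    # ---- environment scan ----------------------------------------------
    if config.do_scan:
        t0 = time.time()
        try:
            grouping = envscan.assign_groups(lat, config.group_breaks)
            env_num = env.drop(columns=[c for c in ("id", "lat", "lon",
                                                    "deme", "site")
                                        if c in env.columns])
            env_tab = envscan.standardize_env(env_num, grouping)
            freqs = envscan.group_allele_freqs(matrix, grouping)
            hwe_ok = hwe_pvalues(matrix) >= config.filters.hwe_alpha
            cov = envscan.estimate_covariance(freqs[:, hwe_ok])
            scan = envscan.bf_scan(matrix, grouping, env_tab, cov,
                                   config.bf_threshold)
            bf_null = envscan.bf_permutation_null(
                matrix, grouping, env_num, cov, config.bf_permutations,
                config.bf_threshold, rng, observed_scan=scan)
            F = envscan.individual_freq_matrix(matrix)
            X = ((env_num - env_num.mean()) / env_num.std(ddof=0)).to_numpy()
            res = envscan.rda_fit(F - F.mean(axis=0), X,
                                  env_names=list(env_num.columns))
            outliers = envscan.rda_outliers(res.locus_scores)
            reg = envscan.outlier_env_regression(matrix, env_num, outliers)
            rda_null = envscan.rda_permutation_null(
                matrix, env_num, config.rda_permutations, rng=rng)
            for a in range(min(3, res.locus_scores.shape[1])):
                scan[f"axis{a + 1}"] = res.locus_scores[:, a]
            scan["rda_outlier"] = outliers
            scan.to_csv(out / "scan.tsv", sep="\t", index=False)
            reg.to_csv(out / "scan_regressions.tsv", sep="\t", index=False)
            bf_null.to_csv(out / "scan_bf_null.tsv", sep="\t", index=False)
            record("scan", {"scan": out / "scan.tsv",
                            "regressions": out / "scan_regressions.tsv",
                            "bf_null": out / "scan_bf_null.tsv"}, t0,
                   bf_candidates=int(scan[[f"{v}_hit" for v in
                                           env_tab.variables]].any(axis=1).sum()),
                   rda_outliers=int(outliers.sum()),
                   significant_associations=int(reg["significant"].sum()),
                   p_outlier_count=float(rda_null["p_outlier_count"]),
                   p_significant_count=float(rda_null["p_significant_count"]))
        except Exception as exc:
            fail("scan", exc)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
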
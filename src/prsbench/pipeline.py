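"""End-to-end orchestration: simulate -> QC -> score -> model -> consistency.

A single config (nested dict, usually parsed from YAML) drives every stage;
one global seed is expanded into per-stage child seeds by a fixed
``SeedSequence`` derivation so stages are individually reproducible. The run
produces a machine-readable report: a per-(GWAS x scope x model x predictor)
table of coefficients, Wald p-values, AUCs and Bonferroni flags, plus the
score-consistency matrix, and a manifest of config/output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import apoe as apoe_mod
from . import consistency as cons_mod
from . import geno_io, prs_engine, qc as qc_mod, riskmodels
from .synthdata import Cohort, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "qc", "prs", "models", "consistency")


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _df_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "checksums": self.checksums,
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
            "versions": self.versions,
        }


@dataclass
class RunResult:
    cohort: Cohort | None
    qc_report: qc_mod.QcReport | None
    scores: dict
    models: pd.DataFrame | None
    consistency: pd.DataFrame | None
    manifest: RunManifest


def validate(config: dict) -> list[str]:
    """Schema and cross-field checks; returns a list of human-readable errors
    (empty = valid)."""
    errors = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    known = set(_STAGES) | {"seed", "outdir", "apoe"}
    for key in config:
        if key not in known:
            errors.append(f"unknown config section {key!r}")
    stages = [s for s in _STAGES if s in config]
    if not stages:
        errors.append("no stages requested")
    sim = config.get("simulate")
    if sim is not None:
        valid_fields = {f.name for f in dc_fields(SimulationConfig)}
        for key in sim or {}:
            if key not in valid_fields:
                errors.append(f"simulate: unknown field {key!r}")
        try:
            SimulationConfig(**{k: _coerce(k, v) for k, v in (sim or {}).items()})
        except (ValueError, TypeError) as err:
            errors.append(f"simulate: {err}")
    prs_cfg = config.get("prs", {})
    grid = prs_cfg.get("pt_grid")
    if grid is not None:
        if any(b <= a for a, b in zip(grid, grid[1:])):
            errors.append("prs: pt_grid must be strictly increasing")
    models_cfg = config.get("models", {})
    which = models_cfg.get("which", ["M1", "M2", "M3", "M4", "M5"])
    bad = [m for m in which if m not in riskmodels.MODEL_PREDICTORS]
    if bad:
        errors.append(f"models: unknown model id(s) {bad}")
    needs_apoe = any(m in ("M1", "M5") for m in which)
    simulated = sim is not None
    if needs_apoe and not simulated and not config.get("apoe"):
        errors.append("models M1/M5 requested but no apoe site spec and no simulation")
    region_modes = models_cfg.get("scopes", ["wholegenome"])
    if "microglia" in region_modes and not simulated and not prs_cfg.get("microglia_bed"):
        errors.append("microglia scope requires a region file or simulated annotation")
    return errors


def _coerce(key: str, value):
    if key == "maf_range" and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def run(config: dict, outdir: str | None = None) -> RunResult:
    """Execute the requested stages in dependency order.

    Only the stages named in the config run; downstream stages require their
    upstream products and fail with the missing stage named.
    """
    errors = validate(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed)
    manifest.versions = {"numpy": np.__version__, "pandas": pd.__version__}
    out = Path(outdir or config.get("outdir", ".")) if (outdir or config.get("outdir")) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cohort = None
    qc_report = None
    scores: dict = {}
    models_df = None
    cons_df = None

    if "simulate" in config:
        t0 = time.perf_counter()
        sim_kwargs = {k: _coerce(k, v) for k, v in (config["simulate"] or {}).items()}
        sim_kwargs.setdefault("seed", child_seed(seed, "simulate"))
        sim_config = SimulationConfig(**sim_kwargs)
        cohort = simulate_cohort(sim_config)
        manifest.timings["simulate"] = time.perf_counter() - t0
        manifest.checksums["phenotype"] = _df_checksum(cohort.phenotype)
        manifest.checksums["sumstats_a"] = _df_checksum(cohort.sumstats_a.table)
        if out is not None:
            geno_io.write_vcf(cohort.genotypes, out / "genotypes.vcf")
            geno_io.write_sumstats(cohort.sumstats_a, out / "sumstats_A.tsv")
            geno_io.write_sumstats(cohort.sumstats_b, out / "sumstats_B.tsv")
            geno_io.write_bed(cohort.microglia, out / "microglia.bed")
            geno_io.write_table(cohort.phenotype, out / "phenotype.tsv")

    if "qc" in config:
        if cohort is None:
            raise RuntimeError("stage 'qc' failed: no genotypes (simulate stage missing)")
        t0 = time.perf_counter()
        qc_cfg = config.get("qc") or {}
        thr = qc_mod.QcThresholds(
            **{k: v for k, v in qc_cfg.items() if k in ("maf_min", "miss_max", "hwe_p_min", "info_min", "kinship_max")}
        )
        filtered, qc_report = qc_mod.variant_qc(cohort.genotypes, thr)
        cohort.genotypes = filtered
        manifest.timings["qc"] = time.perf_counter() - t0
        manifest.checksums["qc_report"] = _df_checksum(qc_report.to_frame())
        if out is not None:
            geno_io.write_table(qc_report.to_frame(), out / "qc_report.tsv")

    ctx = None
    if "prs" in config or "models" in config or "consistency" in config:
        if cohort is None:
            raise RuntimeError("stage 'prs' failed: no cohort available")
        ctx = _build_context(cohort, config, seed)

    if "prs" in config:
        t0 = time.perf_counter()
        scores = _score_stage(ctx, config)
        manifest.timings["prs"] = time.perf_counter() - t0
        if out is not None:
            frames = [s.to_frame() for s in scores.values()]
            geno_io.write_table(pd.concat(frames, ignore_index=True), out / "scores.tsv")
        manifest.checksums["scores"] = hashlib.sha256(
            b"".join(np.ascontiguousarray(s.values).tobytes() for s in scores.values())
        ).hexdigest()

    if "models" in config:
        if not scores:
            raise RuntimeError("stage 'models' failed: no scores (prs stage missing)")
        t0 = time.perf_counter()
        models_df, lps = _model_stage(ctx, scores, config)
        ctx["linear_predictors"] = lps
        manifest.timings["models"] = time.perf_counter() - t0
        manifest.checksums["models"] = _df_checksum(models_df)
        if out is not None:
            geno_io.write_table(models_df, out / "models.tsv")

    if "consistency" in config:
        if not scores:
            raise RuntimeError("stage 'consistency' failed: no scores (prs stage missing)")
        t0 = time.perf_counter()
        cons_df = _consistency_stage(ctx, scores)
        manifest.timings["consistency"] = time.perf_counter() - t0
        manifest.checksums["consistency"] = _df_checksum(cons_df)
        if out is not None:
            geno_io.write_table(cons_df, out / "consistency.tsv")

    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return RunResult(
        cohort=cohort,
        qc_report=qc_report,
        scores=scores,
        models=models_df,
        consistency=cons_df,
        manifest=manifest,
    )


def _build_context(cohort: Cohort, config: dict, seed: int) -> dict:
    """Shared model inputs: covariates (age, sex, PCs), APOE calls, regions."""
    pheno = cohort.phenotype
    n_pcs = int((config.get("models") or {}).get("n_pcs", 8))
    gm = cohort.genotypes
    # PCs are computed excluding the high-LD APOE region (standard long-range-
    # LD exclusion) so a single dense block cannot masquerade as structure
    vf_all = gm.variant_frame()
    outside = ~apoe_mod.apoe_region().contains_mask(vf_all["chrom"], vf_all["pos"])
    gm_pca = gm.subset_variants(outside) if outside.any() else gm
    k = min(n_pcs, gm_pca.n_samples - 1, gm_pca.n_variants)
    pcs = qc_mod.genotype_pca(gm_pca, k)
    covariates = np.column_stack([pheno["age"].to_numpy(), pheno["sex"].to_numpy(), pcs])
    vf = gm.variant_frame()
    apoe_cfg = config.get("apoe") or {}
    e4_id = apoe_cfg.get("e4_site", "rs429358_like")
    e2_id = apoe_cfg.get("e2_site", "rs7412_like")
    ids = vf["id"].tolist()
    try:
        j4, j2 = ids.index(e4_id), ids.index(e2_id)
    except ValueError as err:
        raise RuntimeError(f"APOE defining site not found in genotypes: {err}") from err
    calls = apoe_mod.call_cohort(gm.dosage[:, j4], gm.dosage[:, j2])
    counts = pd.DataFrame(
        {
            "APOE_e2_count": [c.n_e2 for c in calls],
            "APOE_e4_count": [c.n_e4 for c in calls],
        }
    )
    return {
        "cohort": cohort,
        "phenotype": pheno,
        "covariates": covariates,
        "apoe_calls": calls,
        "apoe_counts": counts,
        "apoe_region": apoe_mod.apoe_region(),
        "microglia": cohort.microglia,
    }


def _score_stage(ctx: dict, config: dict) -> dict:
    """C+T scores for both GWAS, both scopes, all three region modes.

    Keys are (gwas, scope, region_mode, pT); within each (gwas, scope) the pT
    maximizing the M5 AUC is additionally exposed under pT='optimal'.
    """
    cohort: Cohort = ctx["cohort"]
    prs_cfg = config.get("prs") or {}
    params = prs_engine.ClumpParams(
        r2_max=float(prs_cfg.get("r2_max", 0.1)),
        window_kb=float(prs_cfg.get("window_kb", 1000.0)),
        pt_grid=tuple(prs_cfg.get("pt_grid", prs_engine.DEFAULT_PT_GRID)),
    )
    scopes = (config.get("models") or {}).get("scopes", ["wholegenome"])
    gm = cohort.genotypes
    apoe_region = ctx["apoe_region"]
    scores: dict = {}
    for gwas_id, ss in (("A", cohort.sumstats_a), ("B", cohort.sumstats_b)):
        aligned_all = prs_engine.harmonize(ss, gm)
        for scope in scopes:
            if scope == "microglia":
                base = prs_engine.restrict_region(aligned_all, gm, ctx["microglia"], "include")
            else:
                base = aligned_all
            for region_mode in ("full", "noAPOE", "APOEonly"):
                if region_mode == "noAPOE":
                    aligned = prs_engine.restrict_region(base, gm, apoe_region, "exclude")
                elif region_mode == "APOEonly":
                    aligned = prs_engine.restrict_region(base, gm, apoe_region, "include")
                else:
                    aligned = base
                clumped = prs_engine.clump(aligned, gm, params)
                for pt in params.pt_grid:
                    sub = prs_engine.threshold(clumped, pt)
                    s = prs_engine.score(gm, sub, method="C+T", region_mode=region_mode, pt=pt)
                    s.gwas_id = gwas_id
                    scores[(gwas_id, scope, region_mode, pt)] = s
    return scores


_SCORE_FOR_MODEL = {"M2": "APOEonly", "M3": "full", "M4": "noAPOE", "M5": "noAPOE"}


def _model_stage(ctx: dict, scores: dict, config: dict):
    """Optimal-pT selection by M5 AUC, then M1-M5 fits per (GWAS, scope)."""
    models_cfg = config.get("models") or {}
    which = tuple(models_cfg.get("which", ["M1", "M2", "M3", "M4", "M5"]))
    scopes = models_cfg.get("scopes", ["wholegenome"])
    grid = riskmodels.TestGrid()
    alpha_per_test = riskmodels.bonferroni_threshold(grid)
    pheno = ctx["phenotype"]
    covs = ctx["covariates"]
    counts = ctx["apoe_counts"]
    pts = sorted({k[3] for k in scores})
    rows = []
    lps = {}
    for scope in scopes:
        scope_which = tuple(m for m in which if scope != "microglia" or m != "M1")
        for gwas_id in ("A", "B"):
            # sweep the grid with the selection model (M5 when present, else last)
            criterion = "M5" if "M5" in scope_which else scope_which[-1]
            by_pt = {}
            for pt in pts:
                sc = {
                    "PRS_full": scores[(gwas_id, scope, "full", pt)].values,
                    "PRS_noAPOE": scores[(gwas_id, scope, "noAPOE", pt)].values,
                    "PRS_APOEonly": scores[(gwas_id, scope, "APOEonly", pt)].values,
                }
                by_pt[pt] = riskmodels.run_models(
                    sc, counts, pheno, covs, which=(criterion,),
                )
            opt_pt = riskmodels.select_pt(by_pt, criterion)
            sc = {
                "PRS_full": scores[(gwas_id, scope, "full", opt_pt)].values,
                "PRS_noAPOE": scores[(gwas_id, scope, "noAPOE", opt_pt)].values,
                "PRS_APOEonly": scores[(gwas_id, scope, "APOEonly", opt_pt)].values,
            }
            results = riskmodels.run_models(
                sc, counts, pheno, covs, which=scope_which,
                bonferroni_alpha=alpha_per_test,
                provenance={"gwas": gwas_id, "scope": scope, "method": "C+T", "pt": opt_pt},
            )
            for r in results:
                rows.extend(r.to_rows())
                lps[(gwas_id, scope, r.model_id)] = r.linear_predictor
            if scope != "microglia" and "M3" in scope_which:
                try:
                    sub = riskmodels.e33_subgroup(
                        sc["PRS_full"], ctx["apoe_calls"], pheno, covs,
                        provenance={"gwas": gwas_id, "scope": scope, "method": "C+T", "pt": opt_pt},
                    )
                    sub.significant = bool(np.min(sub.p) <= alpha_per_test)
                    rows.extend(sub.to_rows())
                except ValueError as err:
                    logger.warning("e3e3 subgroup skipped (%s, %s): %s", gwas_id, scope, err)
    return pd.DataFrame(rows), lps


def _consistency_stage(ctx: dict, scores: dict) -> pd.DataFrame:
    """Pairwise agreement of M3-style scores and M5 linear predictors."""
    entries = []
    lps = ctx.get("linear_predictors", {})
    for (gwas_id, scope, region_mode, pt), s in scores.items():
        if region_mode != "full":
            continue
        entries.append((f"M3:{gwas_id}:{scope}:pT={pt:g}", s.values))
    for (gwas_id, scope, model_id), lp in lps.items():
        if model_id == "M5" and lp is not None:
            entries.append((f"M5lp:{gwas_id}:{scope}", lp))
    results = cons_mod.consistency_matrix(entries, pairs="all")
    return cons_mod.results_frame(results)
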
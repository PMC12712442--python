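"""End-to-end orchestration: simulate/load -> curate -> tree -> signal ->
quantile regressions -> ROPE table -> climate -> bivariate panels.

A single :class:`PipelineConfig` (YAML-loadable) drives the run; every
stochastic stage receives a named substream of the global seed, so toggling
one stage never perturbs another's randomness.  Stage outputs are written as
CSV plus a JSON manifest whose config hash makes reruns reproducible and
lets unchanged stages be reloaded from disk instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, climate, curation, quantreg, signal, simulate, trees

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "render_report"]

DEFAULT_STAGES = ("curate", "signal", "qreg", "ancestral", "climate", "bivariate")


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the study design.

    Either a ``simulate`` block (SimConfig field overrides) or an ``inputs``
    mapping of file paths (frost, drought, el_curves, tree, occurrences,
    grids: {name: path}, heights, model_heights) must be provided.
    """

    outdir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    simulate: dict | None = None
    inputs: dict | None = None
    # analysis parameters
    taus: tuple[float, ...] = (0.1, 0.5, 0.9)
    rope_factor: float = 0.1
    chains: int = 4
    iterations: int = 10_000
    warmup: int = 2_000
    n_perm: int = 1_000
    thin_max: int = 15_000
    thin_km: float = 10.0
    percentile: float = 0.05
    height_rank: int = 10
    height_min_records: int = 100
    rate_screen: tuple[float, float] = (0.2, 9.0)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "taus", "rate_screen"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs a 'simulate' block or 'inputs' paths")
        if self.simulate is None:
            needed = {"frost", "drought"}
            if "signal" in self.stages or "qreg" in self.stages or \
                    "ancestral" in self.stages:
                needed.add("tree")
            if "climate" in self.stages:
                needed.update({"occurrences", "grids"})
            missing = needed - set(self.inputs or {})
            if missing:
                raise ValueError(f"inputs missing for enabled stages: "
                                 f"{sorted(missing)}")
            for key, val in (self.inputs or {}).items():
                paths = val.values() if isinstance(val, dict) else [val]
                for p in paths:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"input {key!r}: {p} not found")


@dataclass
class ResultsBundle:
    curated: pd.DataFrame
    signal: pd.DataFrame | None
    rope: pd.DataFrame | None
    ancestral: pd.DataFrame | None
    climate: pd.DataFrame | None
    bivariate: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def stage_seed(seed: int, stage: str) -> int:
    """Named substream: independent per-stage seeds below 2^31."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _write(outdir: Path, name: str, df: pd.DataFrame) -> None:
    df.to_csv(outdir / f"{name}.csv", index=False)


def _load_cached(outdir: Path, name: str, manifest_path: Path,
                 cfg_hash: str) -> pd.DataFrame | None:
    f = outdir / f"{name}.csv"
    if not (f.exists() and manifest_path.exists()):
        return None
    try:
        old = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return None
    if old.get("config_hash") != cfg_hash:
        return None
    return pd.read_csv(f)


def _simulate_inputs(config: PipelineConfig) -> dict:
    """Generate every pipeline input from the simulate block."""
    overrides = dict(config.simulate or {})
    sim_cfg = simulate.SimConfig(**overrides)
    seed = stage_seed(config.seed, "simulate")
    tree = simulate.sim_tree(sim_cfg.n_species, sim_cfg.birth_rate, seed=seed)
    data, truth = simulate.sim_qr_dataset(tree, sim_cfg, seed=seed + 1)
    truth_df = pd.DataFrame({
        "species": list(data.species),
        "lt50_true": data.y,
        "p50_true": data.x,
        "group": data.group,
    })
    frost_raw, drought_raw, expected = simulate.sim_raw_measurement_tables(
        truth_df, seed=seed + 2)
    occ, grids, occ_truth = simulate.sim_occurrences_and_grids(
        list(data.species)[: min(25, len(data.species))], sim_cfg,
        seed=seed + 3)
    return {"tree": tree, "frost_raw": frost_raw, "drought_raw": drought_raw,
            "expected": expected, "groups": truth_df[["species", "group"]],
            "occurrences": occ, "grids": grids, "truth": truth,
            "sim_config": sim_cfg}


def _load_inputs(config: PipelineConfig) -> dict:
    paths = config.inputs or {}
    out: dict = {}
    out["frost_raw"] = pd.read_csv(paths["frost"])
    out["drought_raw"] = pd.read_csv(paths["drought"])
    if "el_curves" in paths:
        out["el_curves"] = pd.read_csv(paths["el_curves"])
    if "tree" in paths:
        out["tree"] = trees.read_newick(paths["tree"])
    if "groups" in paths:
        out["groups"] = pd.read_csv(paths["groups"])
    if "occurrences" in paths:
        out["occurrences"] = pd.read_csv(paths["occurrences"])
    if "grids" in paths:
        out["grids"] = {name: climate.read_grid(p)
                        for name, p in paths["grids"].items()}
    if "heights" in paths:
        out["heights"] = pd.read_csv(paths["heights"])
    if "model_heights" in paths:
        out["model_heights"] = pd.read_csv(paths["model_heights"])
    return out


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute the enabled stages in dependency order.

    Stage failures abort with the failing stage named; outputs of completed
    stages remain on disk.  Reruns with an identical config reuse cached
    stage outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = outdir / "manifest.json"
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": cfg_hash, "stages": {}}

    inputs = (_simulate_inputs(config) if config.simulate is not None
              else _load_inputs(config))
    bundle = ResultsBundle(curated=pd.DataFrame(), signal=None, rope=None,
                           ancestral=None, climate=None, bivariate=None,
                           manifest=manifest)

    def _run_stage(name: str, fn):
        cached = _load_cached(outdir, name, manifest_path, cfg_hash)
        if cached is not None:
            manifest["stages"][name] = {"rows": int(len(cached)),
                                        "cached": True}
            return cached
        try:
            df = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        _write(outdir, name, df)
        manifest["stages"][name] = {"rows": int(len(df)), "cached": False}
        return df

    # ---- curation (always needed downstream)
    def _curate() -> pd.DataFrame:
        lo, hi = config.rate_screen
        frost, frost_rep = curation.curate_frost(
            inputs["frost_raw"], inputs.get("el_curves"),
            rate_lo=lo, rate_hi=hi)
        drought, drought_rep = curation.curate_drought(inputs["drought_raw"])
        merged, merge_rep = curation.merge_species_table(
            frost, drought, other_traits=inputs.get("groups"))
        manifest["stages"]["curate_reports"] = {
            "frost": frost_rep, "drought": drought_rep, "merge": merge_rep}
        return merged

    curated = _run_stage("curated", _curate)
    bundle.curated = curated

    tree = inputs.get("tree")
    both = curated.dropna(subset=["lt50", "p50"]) if {
        "lt50", "p50"}.issubset(curated.columns) else curated

    if tree is not None and any(s in config.stages
                                for s in ("signal", "qreg", "ancestral")):
        pruned, tip_order = trees.prune_to_overlap(
            tree, set(both["species"]))
        C = trees.vcv(pruned)
        aligned = both.set_index("species").loc[list(C.species)]

    if "signal" in config.stages and tree is not None:
        def _signal() -> pd.DataFrame:
            rows = []
            sseed = stage_seed(config.seed, "signal")
            for trait in ("p50", "lt50"):
                x = aligned[trait].to_numpy(dtype=float)
                rows.append(signal.blomberg_k(
                    x, C, n_perm=config.n_perm, seed=sseed).as_row(trait))
                rows.append(signal.pagel_lambda_ml(x, C).as_row(trait))
            return pd.DataFrame(rows)
        bundle.signal = _run_stage("signal", _signal)

    if "qreg" in config.stages:
        def _qreg() -> pd.DataFrame:
            qseed = stage_seed(config.seed, "qreg")
            rows = []
            for phylo in (False, True):
                if phylo and tree is None:
                    continue
                if phylo:
                    data = quantreg.QRData(
                        y=aligned["lt50"].to_numpy(float),
                        x=aligned["p50"].to_numpy(float),
                        group=aligned["group"].to_numpy(),
                        C=C, species=tuple(C.species))
                else:
                    sub = both.dropna(subset=["group"])
                    data = quantreg.QRData(
                        y=sub["lt50"].to_numpy(float),
                        x=sub["p50"].to_numpy(float),
                        group=sub["group"].to_numpy())
                for tau in config.taus:
                    spec = quantreg.QRSpec(
                        tau=tau, phylo=phylo, chains=config.chains,
                        iterations=config.iterations, warmup=config.warmup,
                        seed=qseed + int(tau * 100) + (1000 if phylo else 0))
                    post = quantreg.fit_qr_mcmc(data, spec)
                    for grp in post.groups:
                        res = quantreg.rope_decision(
                            post.beta(grp), data.y,
                            rope_factor=config.rope_factor,
                            parameter=f"beta[{grp}]")
                        rows.append({
                            "tau": tau, "phylo": phylo, "group": grp,
                            "beta_median": float(np.median(post.beta(grp))),
                            "hdi_lo": res.hdi_lo, "hdi_hi": res.hdi_hi,
                            "rope_lo": res.rope_lo, "rope_hi": res.rope_hi,
                            "verdict": res.verdict})
            return pd.DataFrame(rows)
        bundle.rope = _run_stage("rope", _qreg)

    if "ancestral" in config.stages and tree is not None:
        def _ancestral() -> pd.DataFrame:
            frames = []
            for trait in ("p50", "lt50"):
                df = signal.bm_ancestral_states(
                    pruned, aligned[trait].to_dict())
                df.insert(0, "trait", trait)
                frames.append(df)
            return pd.concat(frames, ignore_index=True)
        bundle.ancestral = _run_stage("ancestral", _ancestral)

    if "climate" in config.stages and "occurrences" in inputs:
        def _climate() -> pd.DataFrame:
            return climate.summarize_species_climate(
                inputs["occurrences"], inputs["grids"],
                max_n=config.thin_max, min_dist_km=config.thin_km,
                percentile=config.percentile,
                seed=stage_seed(config.seed, "climate"))
        bundle.climate = _run_stage("climate", _climate)

    if "bivariate" in config.stages:
        def _bivariate() -> pd.DataFrame:
            frames = []
            trait_cols = [c for c in ("wood_density", "conduit_diameter",
                                      "ks", "max_height", "sla", "leaf_area")
                          if c in curated.columns]
            for resp in ("lt50", "p50"):
                for pred in trait_cols:
                    sub = curated.dropna(subset=[resp, pred, "group"])
                    if len(sub) < 3:
                        continue
                    fit = quantreg.group_line_fit(
                        sub[resp], sub[pred], sub["group"])
                    fit.insert(0, "response", resp)
                    fit.insert(1, "predictor", pred)
                    frames.append(fit)
            if not frames:
                return pd.DataFrame(
                    columns=["response", "predictor", "group", "n", "slope",
                             "intercept", "r2", "p"])
            return pd.concat(frames, ignore_index=True)
        bundle.bivariate = _run_stage("bivariate", _bivariate)

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    bundle.manifest = manifest
    return bundle


def render_report(outdir: str) -> str:
    """Plain-text summary of a results bundle (the slope-verdict table)."""
    outdir_p = Path(outdir)
    lines = []
    manifest = json.loads((outdir_p / "manifest.json").read_text())
    lines.append(f"frostdrought v{manifest['version']} run "
                 f"(seed {manifest['seed']}, config {manifest['config_hash']})")
    rope_f = outdir_p / "rope.csv"
    if rope_f.exists():
        rope = pd.read_csv(rope_f)
        lines.append("\nSlope HDI vs ROPE (quantile x group x phylogeny):")
        for _, r in rope.iterrows():
            model = "phylo" if r["phylo"] else "non-phylo"
            lines.append(
                f"  tau={r['tau']:<4} {model:<9} {r['group']:<22} "
                f"beta={r['beta_median']:+.3f} "
                f"HDI=[{r['hdi_lo']:+.3f}, {r['hdi_hi']:+.3f}] "
                f"-> {r['verdict']}")
    sig_f = outdir_p / "signal.csv"
    if sig_f.exists():
        sig = pd.read_csv(sig_f)
        lines.append("\nPhylogenetic signal:")
        for _, r in sig.iterrows():
            p1 = "" if pd.isna(r.get("p_vs_1")) else f" p_vs_1={r['p_vs_1']:.3g}"
            lines.append(f"  {r['trait']:<6} {r['method']:<7} "
                         f"{r['estimate']:.3f} p_vs_0={r['p_vs_0']:.3g}{p1} "
                         f"(n={r['n']})")
    return "\n".join(lines)
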
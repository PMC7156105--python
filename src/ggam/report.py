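"""Pipeline orchestration: simulate/load -> validate -> q & A-inverse -> fit
-> derive -> report, with reproducibility metadata.

A run directory is a pure function of (inputs, config, seed): every file it
contains is written deterministically (no timestamps), and the manifest
records the config hash, seed, and library versions needed to re-run any
stage in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .derive import back_transform, derive_all
from .model import (
    ChainConfig,
    FitDiagnosticsWarning,
    PosteriorSamples,
    PriorSpec,
    adaptive_thin,
    build_design,
    fit_mcmc,
    predict_genetic_values,
    read_broods,
    summarize,
)
from .pedigree import (
    GroupCoefficients,
    Pedigree,
    assign_genetic_groups,
    compute_A_inverse,
    compute_q,
    mean_pairwise_kinship,
    prune_pedigree,
    read_pedigree,
    write_A_inverse,
    write_pedigree,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "describe_dataset"]


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 1
    pedigree: str | None = None
    broods: str | None = None
    simulate: dict | None = None  # SimulationConfig overrides; presence triggers simulation
    cutoff_year: int | None = None
    baseline_year: int | None = None
    chain: dict = dataclasses.field(default_factory=dict)
    priors: dict = dataclasses.field(default_factory=dict)
    scenarios: list[dict] = dataclasses.field(default_factory=list)
    auto_thin: bool = True
    store_animal: bool = True

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("pedigree", "broods"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"config must give either a simulate section or a {name} path")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
        self.chain_config()
        self.prior_spec()

    def chain_config(self) -> ChainConfig:
        cc = ChainConfig(**{**dict(seed=self.seed), **self.chain})
        cc.validate()
        return cc

    def prior_spec(self) -> PriorSpec:
        ps = PriorSpec(**self.priors)
        ps.validate()
        return ps

    def canonical(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def describe_dataset(
    ped: Pedigree, broods: pd.DataFrame, q: GroupCoefficients | None = None
) -> dict:
    """Descriptive summary: counts, EPP rate, q moments, mean kinship."""
    females = sorted(set(broods["female_id"].astype(str)))
    males = sorted(set(broods["male_id"].astype(str)))
    per_year = broods.groupby("year").size()
    out = {
        "n_broods": int(len(broods)),
        "n_females": len(females),
        "n_males": len(males),
        "n_pairs": int(broods[["female_id", "male_id"]].drop_duplicates().shape[0]),
        "n_years": int(broods["year"].nunique()),
        "broods_per_year_mean": float(per_year.mean()),
        "broods_per_year_sd": float(per_year.std(ddof=1)) if len(per_year) > 1 else 0.0,
        "epp_rate": float(broods["n_epo"].sum() / broods["n_offspring"].sum()),
        "n_pedigree": ped.n,
        "n_pedigree_founders": int(
            sum(1 for d, s in zip(ped.df["dam"], ped.df["sire"]) if d is None and s is None)
        ),
    }
    if q is not None:
        qf = np.array([q[i] for i in females])
        qm = np.array([q[i] for i in males])
        out.update(
            q_mean_female=float(qf.mean()),
            q_sd_female=float(qf.std(ddof=1)) if len(qf) > 1 else 0.0,
            q_mean_male=float(qm.mean()),
            q_sd_male=float(qm.std(ddof=1)) if len(qm) > 1 else 0.0,
            var_q=q.var_q,
        )
    km, ks = mean_pairwise_kinship(ped, females + males)
    out["kinship_mean"] = km
    out["kinship_sd"] = ks
    return out


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_text_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(df.to_string(float_format=lambda v: f"{v:.4f}"))
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages into ``cfg.out_dir``; returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    diagnostics: list[str] = []
    try:
        # ---- stage: data -------------------------------------------------
        stage = "data"
        if cfg.simulate is not None:
            sim_cfg = SimulationConfig(**{**dict(seed=cfg.seed), **cfg.simulate})
            ds = simulate_dataset(sim_cfg)
            ped_full, broods = ds.pedigree, ds.broods
            write_pedigree(ped_full, out / "pedigree.csv")
            broods.to_csv(out / "broods.csv", index=False)
            ds.truth.to_csv(out / "truth.csv")
        else:
            ped_full = read_pedigree(cfg.pedigree)
            broods = read_broods(cfg.broods)

        # ---- stage: pedigree ---------------------------------------------
        stage = "pedigree"
        phenotyped = set(broods["female_id"].astype(str)) | set(broods["male_id"].astype(str))
        ped = prune_pedigree(ped_full, phenotyped)
        write_pedigree(ped, out / "pedigree_pruned.csv")
        groups = assign_genetic_groups(ped, cfg.cutoff_year)
        q = compute_q(ped, groups, phenotyped=phenotyped)
        rel = compute_A_inverse(ped)
        pd.DataFrame({"id": q.q.index, "q": q.q.to_numpy()}).to_csv(out / "q.csv", index=False)
        write_A_inverse(rel, out / "a_inverse.tsv")
        _write_json(describe_dataset(ped, broods, q), out / "describe.json")

        # ---- stage: fit ---------------------------------------------------
        stage = "fit"
        design = build_design(ped, q, broods, baseline_year=cfg.baseline_year, rel=rel)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", FitDiagnosticsWarning)
            samples = fit_mcmc(
                design,
                cfg.prior_spec(),
                cfg.chain_config(),
                store_animal=cfg.store_animal,
            )
            if cfg.auto_thin:
                samples = adaptive_thin(samples)
            diagnostics = [str(w.message) for w in caught if issubclass(w.category, FitDiagnosticsWarning)]
        samples.params.to_csv(out / "draws.csv", index=False)
        summ = summarize(samples.params)
        summ.to_csv(out / "summary.csv")
        _write_json(summ.to_dict(orient="index"), out / "summary.json")
        _write_text_table(summ, out / "summary.txt")

        # ---- stage: derive ------------------------------------------------
        stage = "derive"
        derived = derive_all(samples, q.var_q)
        derived.draws.to_csv(out / "derived_draws.csv", index=False)
        dsumm = summarize(derived.draws.dropna())
        dsumm.to_csv(out / "derived_summary.csv")
        _write_json(
            {**dsumm.to_dict(orient="index"), "var_q": q.var_q},
            out / "derived_summary.json",
        )
        _write_text_table(dsumm, out / "derived_summary.txt")

        # ---- stage: report ------------------------------------------------
        stage = "report"
        if cfg.scenarios:
            rates = back_transform(samples, cfg.scenarios, design.baseline_year)
            rates.to_csv(out / "scenario_draws.csv", index=False)
            rsumm = summarize(rates)
            if rates.shape[1] == 2:
                diff = rates.iloc[:, 0] - rates.iloc[:, 1]
                rsumm.loc["difference"] = summarize(diff.to_frame("difference")).loc["difference"]
            rsumm.to_csv(out / "scenarios.csv")
            _write_json(rsumm.to_dict(orient="index"), out / "scenarios.json")
        if cfg.store_animal:
            pred = predict_genetic_values(samples, q)
            pred.to_csv(out / "predicted_values.csv")
    except Exception as exc:
        dump = out / "failure.json"
        _write_json({"stage": stage, "error": repr(exc)}, dump)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    # ---- manifest (no timestamps: runs are bit-reproducible) -------------
    cfg_text = yaml.safe_dump(cfg.canonical(), sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "ggam": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "fit_diagnostics": diagnostics,
        "stages": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    _write_json(manifest, out / "manifest.json")
    return out
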
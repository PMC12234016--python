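"""End-to-end study driver.

Runs the full analysis sequence on a canonical dataset (loaded from CSV or
simulated from a configured truth): descriptives and twin correlations,
per-wave univariate ACE/ADE/AE fits with AIC selection, the multivariate
Cholesky decomposition and common pathway model, optional item-level
EFA/CFA, and (for multi-variable data) the correlated-factor model.  Every
random step is seeded; the report bundle is a structured JSON plus CSV
tables, and two runs with the same configuration and seed are byte
identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import models, selection
from .biometric import (
    FAMILIES,
    build_cholesky,
    build_common_pathway,
    build_correlated_factors,
    build_univariate,
    standardize,
)
from .data import (
    TwinDataset,
    cronbach_alpha_per_wave,
    crosstwin_correlations,
    descriptives,
    load_csv,
    longitudinal_correlations,
    select_one_twin,
    sqrt_transform,
)
from .factors import cfa, efa, split_sample
from .simulate import SimConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one study run."""

    input_csv: str | None = None
    simulate: dict | None = None       # SimConfig keyword arguments
    sqrt_transform: bool = True
    families: tuple[str, ...] = ("ACE", "ADE", "AE")
    stages: tuple[str, ...] = (
        "describe", "univariate", "cholesky", "common_pathway",
    )
    include_saturated: bool = False
    analyze_items: bool = True
    seed: int = 0
    n_starts: int = 2
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("families", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _wave_groups(groups, W, wave):
    """Per-wave two-column (twin1, twin2) group arrays, empty rows dropped."""
    out = []
    for g in groups:
        sub = g[:, [wave, W + wave]]
        out.append(models.drop_empty_rows(sub))
    return out


def _fit_family_set(builder, groups, families, n_starts, seed):
    fits = []
    for fam in families:
        comps = FAMILIES[fam]
        try:
            spec = builder(comps)
            fits.append(
                models.fit(spec, groups, n_starts=n_starts, seed=seed,
                           standard_errors=False)
            )
        except ValueError as exc:  # e.g. family invalid for this structure
            logger.warning("skipping family %s: %s", fam, exc)
    return fits


def _round_floats(obj, digits=10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def run_study(config: RunConfig) -> dict:
    """Execute the configured analysis sequence and write the report bundle.

    Stage failures are caught and recorded under ``errors``; the remaining
    stages still run on whatever data is available.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": config.seed, "errors": {}}

    # -- data ---------------------------------------------------------------
    if config.input_csv:
        data = load_csv(config.input_csv)
        report["input"] = {"path": str(config.input_csv)}
    elif config.simulate:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = SimConfig(**sim_kwargs)
        data, truth = simulate(cfg)
        (outdir / "truth.json").write_text(
            json.dumps(_round_floats(truth.to_dict()), indent=2, sort_keys=True)
        )
        data.write_csv(outdir / "simulated.csv")
        report["input"] = {"simulated": cfg.structure,
                           "n_mz": cfg.n_mz, "n_dz": cfg.n_dz}
    else:
        raise ValueError("config must provide input_csv or a simulation truth")

    report["n_pairs"] = data.n_pairs
    raw = data
    # item-only datasets carry no score columns; the score-based stages are
    # skipped and only the item-level analyses apply
    has_scores = data.score_column(1, 1) in data.df.columns
    if config.sqrt_transform and has_scores:
        data = sqrt_transform(data)
    groups = data.group_arrays() if has_scores else []
    W = data.n_waves * data.n_vars if has_scores else 0

    # -- descriptives -------------------------------------------------------
    if "describe" in config.stages:
        try:
            if has_scores:
                desc = descriptives(raw)
                desc.to_csv(outdir / "descriptives.csv", index=False)
                report["descriptives"] = _round_floats(
                    desc.to_dict(orient="records"))
                if data.n_waves >= 2:
                    lc = longitudinal_correlations(data, one_per_pair=True,
                                                   seed=config.seed)
                    lc.to_csv(outdir / "longitudinal_correlations.csv",
                              index=False)
                    report["longitudinal_correlations"] = _round_floats(
                        lc.to_dict(orient="records"))
                ct = crosstwin_correlations(data)
                ct.to_csv(outdir / "crosstwin_correlations.csv", index=False)
                report["crosstwin_correlations"] = _round_floats(
                    ct.to_dict(orient="records"))
            if data.n_items >= 2:
                report["cronbach_alpha"] = _round_floats(
                    {str(k): v for k, v in cronbach_alpha_per_wave(raw).items()}
                )
        except Exception as exc:
            report["errors"]["describe"] = str(exc)

    # -- univariate models per wave -----------------------------------------
    if "univariate" in config.stages:
        try:
            uni = {}
            for w in range(W):
                wg = _wave_groups(groups, W, w)
                fits = []
                for fam in config.families:
                    spec = build_univariate(fam, data=wg)
                    fits.append(models.fit(spec, wg, n_starts=config.n_starts,
                                           seed=config.seed,
                                           standard_errors=False))
                table = selection.compare(fits)
                best = selection.best_model(table)
                best_fit = next(f for f in fits if f.model == best)
                est = standardize(best_fit)
                uni[f"wave_{w + 1}"] = {
                    "comparison": _round_floats(table.to_dict(orient="records")),
                    "best": best,
                    "shares": _round_floats(
                        {c: float(est.total_shares[c][0])
                         for c in est.components}),
                }
            report["univariate"] = uni
        except Exception as exc:
            report["errors"]["univariate"] = str(exc)

    # -- multivariate models --------------------------------------------------
    multivariate_fits = []
    if "cholesky" in config.stages and W >= 2:
        try:
            fits = _fit_family_set(
                lambda comps: build_cholesky(W, comps, data=groups),
                groups, config.families, config.n_starts, config.seed)
            table = selection.compare(fits)
            best = selection.best_model(table)
            best_fit = next(f for f in fits if f.model == best)
            est = standardize(best_fit)
            report["cholesky"] = {
                "comparison": _round_floats(table.to_dict(orient="records")),
                "best": best,
                "estimates": _round_floats(est.to_dict()),
            }
            multivariate_fits += fits
        except Exception as exc:
            report["errors"]["cholesky"] = str(exc)

    if "common_pathway" in config.stages and W >= 3:
        try:
            fits = _fit_family_set(
                lambda comps: build_common_pathway(W, comps, data=groups),
                groups, config.families, config.n_starts, config.seed)
            table = selection.compare(fits)
            best = selection.best_model(table)
            best_fit = next(f for f in fits if f.model == best)
            est = standardize(best_fit)
            report["common_pathway"] = {
                "comparison": _round_floats(table.to_dict(orient="records")),
                "best": best,
                "estimates": _round_floats(est.to_dict()),
                "latent_heritability": _round_floats(est.latent_heritability),
            }
            multivariate_fits += fits
        except Exception as exc:
            report["errors"]["common_pathway"] = str(exc)

    if "correlated_factors" in config.stages and data.n_vars >= 2:
        try:
            fits = _fit_family_set(
                lambda comps: build_correlated_factors(
                    data.n_vars * data.n_waves, comps, data=groups),
                groups, config.families, config.n_starts, config.seed)
            table = selection.compare(fits)
            best = selection.best_model(table)
            est = standardize(next(f for f in fits if f.model == best))
            report["correlated_factors"] = {
                "comparison": _round_floats(table.to_dict(orient="records")),
                "best": best,
                "estimates": _round_floats(est.to_dict()),
            }
        except Exception as exc:
            report["errors"]["correlated_factors"] = str(exc)

    if config.include_saturated and multivariate_fits:
        try:
            sat = models.fit_saturated(groups)
            sat_c = models.fit_saturated(groups, constrained=True)
            rows = selection.compare(
                multivariate_fits + [sat, sat_c], check_data=False)
            rows.to_csv(outdir / "fit_comparison.csv", index=False)
            report["saturated"] = {
                "minus2ll": _round_floats(sat.minus2ll),
                "constrained_minus2ll": _round_floats(sat_c.minus2ll),
                "comparison": _round_floats(rows.to_dict(orient="records")),
            }
        except Exception as exc:
            report["errors"]["saturated"] = str(exc)

    # -- item-level factor structure ------------------------------------------
    if config.analyze_items and data.n_items >= 2:
        try:
            frame = select_one_twin_items(raw, seed=config.seed)
            explore, confirm = split_sample(frame, 0.7, seed=config.seed)
            efa_res = efa(explore.to_numpy(float), seed=config.seed)
            report["efa"] = _round_floats(efa_res.to_dict())
            if efa_res.n_factors >= 1 and (efa_res.assignment >= 0).any():
                pattern = np.zeros((raw.n_items, efa_res.n_factors), dtype=bool)
                for i, a in enumerate(efa_res.assignment):
                    if a >= 0:
                        pattern[i, a] = True
                used = pattern.any(axis=1)
                cfa_res = cfa(confirm.to_numpy(float)[:, used],
                              pattern[used][:, pattern[used].any(axis=0)],
                              seed=config.seed)
                report["cfa"] = _round_floats(cfa_res.to_dict())
        except Exception as exc:
            report["errors"]["factor_structure"] = str(exc)

    text = json.dumps(_round_floats(report), indent=2, sort_keys=True)
    (outdir / "report.json").write_text(text)
    return report


def select_one_twin_items(data: TwinDataset, wave: int = 1, seed: int = 0):
    """Item responses of one randomly selected twin per pair at one wave."""
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=data.n_pairs)
    a1 = data.df[data.item_columns(1, wave)].to_numpy(float)
    a2 = data.df[data.item_columns(2, wave)].to_numpy(float)
    import pandas as pd

    return pd.DataFrame(
        np.where((pick == 1)[:, None], a1, a2),
        columns=[f"item_{i + 1}" for i in range(data.n_items)],
    )
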
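"""End-to-end orchestration: seasonality -> chronotype clustering (seasonal
and non-seasonal fractions independently) -> environmental correlation ->
enrichment -> variants, driven by a single YAML/dict config, with a run
manifest and a summary report.

All outputs are plain TSV/JSON with fixed float formatting, so a re-run with
the same config and seed is byte-identical.  The manifest records the config
snapshot, seed, input checksums and package version; a wall-clock timestamp
is recorded only on request (``record_time=True``), because it would break
byte-level reproducibility.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronoclustr import bootstrap_consensus, save_model
from .core_data import (align_to_grid, minmax_scale, read_abundance_table,
                        read_env_table, zscore_matrix)
from .enrichment import category_ratios, enrichment_test
from .env_assoc import chronotype_medoids, correlate_medoids
from .seasonality import classify_collection, harmonic_regression, time_decay
from .variants import (attach_coverage, curves_to_frame, eligibility,
                       fit_decay_model, load_variants, recurrence_test,
                       shift_matrix, shift_summary)

log = logging.getLogger("chronotyper")

_FLOAT_FMT = "%.10g"

DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "gtest_mode": "global",
    "subgroup_size": 100,
    "n_bootstraps": 100,
    "k_max_subgroup": 20,
    "clustering_method": "tsclust",
    "consensus_linkage": "average",
    "harmonic_period": 12,
    "holm_family": "per-medoid",
    "eligibility_mode": "any-sample",
    "enrichment_alternative": "greater",
    "inputs": {},
}


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of a census count, rounded to the reporting precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path_or_dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg.update(user)
    return cfg


def write_manifest(out_dir: Path, cfg: dict, record_time: bool = False) -> None:
    inputs = {k: _sha256(Path(v)) for k, v in cfg.get("inputs", {}).items()
              if v and Path(v).is_file()}
    manifest = {"config": cfg, "seed": cfg["seed"], "input_checksums": inputs,
                "version": __version__,
                "timestamp": _dt.datetime.now().isoformat() if record_time else None}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def run_all(config, out_dir, record_time: bool = False) -> dict:
    """Execute every stage for which the config provides inputs.

    Required input: ``inputs.abundance``.  Optional: ``inputs.env``,
    ``inputs.annotations``, ``inputs.vcf_dir`` + ``inputs.coverage``.
    Missing optional inputs skip their stage with a warning.  Returns a dict
    of the principal in-memory results.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    if "abundance" not in inputs:
        raise ValueError("config inputs.abundance is required")
    results: dict = {}

    # --- seasonality ------------------------------------------------------
    am = align_to_grid(read_abundance_table(inputs["abundance"]))
    seasonal, non_seasonal, stab = classify_collection(
        am, alpha=cfg["alpha"], mode=cfg["gtest_mode"])
    stab.to_csv(out / "seasonality.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
    curve = time_decay(am)
    try:
        harmonic_regression(curve, period=cfg["harmonic_period"])
    except ValueError as exc:
        log.warning("harmonic regression skipped: %s", exc)
    curve.to_frame().to_csv(out / "time_decay.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
    results["seasonal"], results["non_seasonal"] = seasonal, non_seasonal
    results["abundance"] = am

    # --- chronotypes per fraction ----------------------------------------
    Z, _ = zscore_matrix(am.values)
    idx = {v: i for i, v in enumerate(am.votu_ids)}
    models = {}
    for name, ids in (("seasonal", seasonal), ("non_seasonal", non_seasonal)):
        if len(ids) < 10:
            log.warning("fraction %s has %d vOTUs; clustering skipped",
                        name, len(ids))
            continue
        model = bootstrap_consensus(
            Z[[idx[v] for v in ids]], ids,
            n_bootstraps=cfg["n_bootstraps"], subgroup_size=cfg["subgroup_size"],
            seed=cfg["seed"], k_max_subgroup=cfg["k_max_subgroup"],
            method=cfg["clustering_method"],
            consensus_linkage=cfg["consensus_linkage"])
        save_model(model, out / f"chronotypes_{name}")
        models[name] = model
    results["models"] = models

    # --- environmental correlation ---------------------------------------
    if "env" in inputs and models:
        env = minmax_scale(read_env_table(inputs["env"]))
        frames = []
        for name, model in models.items():
            medoids = chronotype_medoids(
                Z[[idx[v] for v in model.votu_ids]], model.votu_ids,
                model.memberships)
            df = correlate_medoids(am, medoids, env, alpha=cfg["alpha"])
            df.insert(0, "fraction", name)
            frames.append(df)
        envcorr = pd.concat(frames, ignore_index=True)
        envcorr.to_csv(out / "envcorr.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
        results["envcorr"] = envcorr
    elif "env" not in inputs:
        log.warning("no env table configured; environmental correlation skipped")

    # --- enrichment -------------------------------------------------------
    if "annotations" in inputs and len(models) == 2:
        ann = pd.read_csv(inputs["annotations"], sep="\t")
        memberships, seasonal_set = {}, set()
        offset = 0
        for name in ("seasonal", "non_seasonal"):
            model = models[name]
            for v, c in model.memberships.items():
                memberships[v] = c + offset
            if name == "seasonal":
                seasonal_set = {c + offset for c in model.memberships.values()}
            offset += model.k_final
        ann = ann[ann["votu_id"].astype(str).isin(memberships)]
        ratios = category_ratios(ann, memberships, seasonal_set)
        enr = enrichment_test(ratios, alpha=cfg["alpha"],
                              alternative=cfg["enrichment_alternative"])
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
        results["enrichment"] = enr
    elif "annotations" not in inputs:
        log.warning("no annotation table configured; enrichment skipped")

    # --- variants ---------------------------------------------------------
    if "vcf_dir" in inputs and "coverage" in inputs:
        coverage = pd.read_csv(inputs["coverage"], sep="\t")
        vcfs = sorted(Path(inputs["vcf_dir"]).glob("*.vcf"))
        date_to_month = dict(zip(am.dates, am.month_index))
        vcf_by_month = {}
        for p in vcfs:
            if p.stem not in date_to_month:
                raise ValueError(f"VCF sample date {p.stem} not on the grid")
            vcf_by_month[int(date_to_month[p.stem])] = p
        profiles = load_variants(vcf_by_month)
        attach_coverage(profiles, coverage)
        strict = eligibility(coverage, mode="all-samples")
        sm = shift_matrix(profiles, strict)
        if len(sm):
            summ = shift_summary(sm)
            summ.to_csv(out / "shift_medians.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
            fits = {}
            for side, sign in (("positive", 1), ("negative", -1)):
                if (np.sign(summ["shift"]) == sign).sum() >= 6:
                    fits[side] = fit_decay_model(summ["shift"],
                                                 summ["median_shared"],
                                                 side=side, seed=cfg["seed"])
            (out / "decay_fit.json").write_text(
                json.dumps(fits, indent=2, sort_keys=True) + "\n")
            results["decay_fits"] = fits
        loose = eligibility(coverage, mode=cfg["eligibility_mode"])
        tested = {v: p for v, p in profiles.items() if loose.get(v, False)}
        curves, frac = recurrence_test(tested, alpha=cfg["alpha"])
        curves_to_frame(curves).to_csv(out / "shared_curves.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)
        pd.DataFrame({"metric": ["recurrent_fraction"], "value": [frac]}).to_csv(
            out / "recurrence.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        results["recurrent_fraction"] = frac
    elif "vcf_dir" not in inputs:
        log.warning("no VCFs configured; variant analysis skipped")

    write_manifest(out, cfg, record_time=record_time)
    return results


def report(out_dir) -> pd.DataFrame:
    """Summary table of a completed run: fraction sizes and percentages,
    chronotype counts, enrichment hits and the recurrent fraction."""
    out = Path(out_dir)
    if not (out / "manifest.json").is_file():
        raise ValueError(f"{out} is not a completed run (no manifest)")
    rows = []
    stab = pd.read_csv(out / "seasonality.tsv", sep="\t")
    n = len(stab)
    n_sea = int((stab["label"] == "seasonal").sum())
    rows += [("n_votus", n), ("n_seasonal", n_sea), ("n_non_seasonal", n - n_sea),
             ("pct_seasonal", percent(n_sea, n)),
             ("pct_non_seasonal", percent(n - n_sea, n))]
    for name in ("seasonal", "non_seasonal"):
        f = out / f"chronotypes_{name}" / "memberships.tsv"
        if f.is_file():
            mem = pd.read_csv(f, sep="\t")
            rows.append((f"n_chronotypes_{name}", mem["chronotype"].nunique()))
        else:
            rows.append((f"n_chronotypes_{name}", "skipped"))
    f = out / "enrichment.tsv"
    if f.is_file():
        enr = pd.read_csv(f, sep="\t")
        rows.append(("n_enriched_categories", int(enr["significant"].sum())))
    f = out / "recurrence.tsv"
    if f.is_file():
        rec = pd.read_csv(f, sep="\t")
        rows.append(("recurrent_fraction", float(rec["value"].iloc[0])))
    df = pd.DataFrame(rows, columns=["metric", "value"])
    df.to_csv(out / "report.tsv", sep="\t", index=False)
    return df
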
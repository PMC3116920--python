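"""End-to-end orchestration: reconstruct -> screen -> fit -> regress.

A single YAML config drives the stages; every intermediate is persisted
in a standard text format under the output directory and a JSON manifest
records parameters, seeds and content checksums. Stages are independently
re-runnable: a stage is skipped when all of its outputs exist and its
inputs' checksums match the previous manifest, so deleting one
intermediate recomputes only that stage and anything downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import TreeEnsemble, alternate_states, combine_over_trees
from .dose_response import DoseResponseDataset, fit_hill, sensitivity_table
from .io import AMINO_ACIDS, read_alignment, read_table, read_tree
from .likelihood import optimize
from .screen import ConservativeRule, packaged_contact_sites, screen_alignment_pair
from .stability import (
    ddg_histogram,
    regression_with_and_without,
    summarize_runs,
)
from .substitution_models import build_model

log = logging.getLogger("ancres.pipeline")

DEFAULTS = {
    "alt_threshold": 0.20,   # plausible-alternate-state posterior cutoff
    "fold_limit": 2.0,       # nonresponder rule: <2-fold activation ...
    "conc_limit": 1e-6,      # ... at 1 uM hormone
    "ddg_runs": 5,           # energy-function runs averaged per mutant
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a YAML mapping")
    base = Path(path).parent

    def resolve(section: str, key: str) -> None:
        if section in cfg and key in cfg[section]:
            val = cfg[section][key]
            vals = val if isinstance(val, list) else [val]
            resolved = [str((base / v).resolve()) if not Path(v).is_absolute() else v
                        for v in vals]
            cfg[section][key] = resolved if isinstance(val, list) else resolved[0]

    for sec, keys in {
        "reconstruct": ["alignment", "trees"],
        "screen": ["ancestor", "derived", "other", "contacts"],
        "fit": ["table"],
        "regress": ["ddg", "ec50"],
    }.items():
        for k in keys:
            resolve(sec, k)
    return cfg


def validate_config(cfg: dict) -> None:
    """Fail fast: every referenced path must exist, thresholds be legal."""
    missing = []
    for sec, keys in {
        "reconstruct": ["alignment", "trees"],
        "screen": ["ancestor", "derived", "other", "contacts"],
        "fit": ["table"],
        "regress": ["ddg", "ec50"],
    }.items():
        if sec not in cfg:
            continue
        for k in keys:
            val = cfg[sec].get(k)
            if val is None:
                continue
            for p in val if isinstance(val, list) else [val]:
                if not Path(p).exists():
                    missing.append(p)
    if missing:
        raise PipelineError(f"missing input file(s): {missing}")
    thr = cfg.get("reconstruct", {}).get("alt_threshold", DEFAULTS["alt_threshold"])
    if not 0.0 < thr < 1.0:
        raise PipelineError(f"alternate-state threshold out of range: {thr}")


def _stage_inputs(cfg: dict, stage: str) -> list[Path]:
    keys = {
        "reconstruct": ["alignment", "trees"],
        "screen": ["ancestor", "derived", "other", "contacts"],
        "fit": ["table"],
        "regress": ["ddg", "ec50"],
    }[stage]
    paths = []
    for k in keys:
        val = cfg[stage].get(k)
        if val is None:
            continue
        paths += [Path(p) for p in (val if isinstance(val, list) else [val])]
    return paths


def _fresh(stage: str, inputs: list[Path], outputs: list[Path], prev: dict) -> bool:
    """True when the stage's persisted outputs are current."""
    if not all(p.exists() for p in outputs):
        return False
    rec = prev.get("stages", {}).get(stage)
    if rec is None:
        return False
    in_sums = {str(p): _sha256(p) for p in inputs}
    return rec.get("input_checksums") == in_sums


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; return the run manifest (also written
    to ``manifest.json`` in the output directory)."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    out = Path(output_dir or config.get("output_dir", "ancres_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest_path = out / "manifest.json"
    prev = {}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
    manifest = {"version": __version__, "seed": seed, "stages": {}}

    stage_order = ["reconstruct", "screen", "fit", "regress"]
    for stage in stage_order:
        if stage not in config:
            continue
        t0 = time.monotonic()
        inputs = _stage_inputs(config, stage)
        runner = globals()[f"_run_{stage}"]
        outputs = runner(config, out, dry=True)
        if _fresh(stage, inputs, outputs, prev):
            log.info("stage %s: outputs current, skipped", stage)
            manifest["stages"][stage] = prev["stages"][stage]
            continue
        try:
            outputs = runner(config, out, dry=False)
        except Exception as exc:
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "parameters": config[stage],
            "input_checksums": {str(p): _sha256(p) for p in inputs},
            "output_checksums": {str(p): _sha256(p) for p in outputs},
        }
        log.info("stage %s: done in %.2fs", stage, time.monotonic() - t0)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# -- stages -----------------------------------------------------------------


def _run_reconstruct(cfg: dict, out: Path, dry: bool) -> list[Path]:
    c = cfg["reconstruct"]
    outputs = [out / "ancestor.fasta", out / "posteriors.tsv", out / "alternates.tsv"]
    if dry:
        return outputs
    aln = read_alignment(c["alignment"])
    trees = [read_tree(p) for p in c["trees"]]
    alpha = c.get("alpha", "auto")
    model = build_model(alpha=1.0 if alpha == "auto" else float(alpha),
                        K=int(c.get("gamma_categories", 4)))
    fitted_trees, lnls, fitted_alpha = [], [], model.alpha
    for tree in trees:
        res = optimize(tree, aln, model, optimize_alpha=(alpha == "auto"))
        fitted_trees.append(res.tree)
        lnls.append(res.lnl)
        fitted_alpha = res.alpha
    model = model.with_alpha(fitted_alpha)
    if "weights" in c:
        ens = TreeEnsemble(fitted_trees, np.asarray(c["weights"], dtype=float))
    else:
        log.warning("no tree weights supplied; approximating from likelihoods")
        ens = TreeEnsemble.from_log_likelihoods(fitted_trees, lnls)
    recon = combine_over_trees(ens, aln, model, c["node"])
    outputs[0].write_text(f">{c['node']}\n{recon.ml_sequence}\n")
    pp = pd.DataFrame(recon.pp, columns=list(AMINO_ACIDS))
    pp.insert(0, "site", np.arange(1, recon.nsites + 1))
    pp.to_csv(outputs[1], sep="\t", index=False, float_format="%.6f")
    thr = float(c.get("alt_threshold", DEFAULTS["alt_threshold"]))
    alts = alternate_states(recon, thr)
    with open(outputs[2], "w") as fh:
        fh.write("site\tstate\tpp\n")
        for site, states in sorted(alts.items()):
            for aa, p in states:
                fh.write(f"{site}\t{aa}\t{p:.4f}\n")
    return outputs


def _run_screen(cfg: dict, out: Path, dry: bool) -> list[Path]:
    c = cfg["screen"]
    outputs = [out / "screen.tsv"]
    if dry:
        return outputs
    anc = read_alignment(c["ancestor"])
    der = read_alignment(c["derived"])
    other = read_alignment(c["other"]) if c.get("other") else None
    if c.get("contacts"):
        contacts = {
            int(tok)
            for line in Path(c["contacts"]).read_text().splitlines()
            if line.strip() and not line.startswith("#")
            for tok in line.split()
        }
    else:
        log.warning("no contact annotation supplied; using the packaged one")
        contacts = packaged_contact_sites()
    rule = (ConservativeRule.from_pair_list(c["conservative_pairs"])
            if c.get("conservative_pairs") else ConservativeRule())
    report = screen_alignment_pair(anc, der, other, contacts, rule)
    pd.DataFrame(report.rows()).to_csv(outputs[0], sep="\t", index=False)
    return outputs


def _run_fit(cfg: dict, out: Path, dry: bool) -> list[Path]:
    c = cfg["fit"]
    outputs = [out / "sensitivity.tsv", out / "logec50_matrix.tsv"]
    if dry:
        return outputs
    df = read_table(c["table"], "dose_response")
    fix_slope = c.get("fix_slope")
    if fix_slope is None:
        log.warning("Hill slope left free (bounded); set fix_slope to pin it")
    fits = {}
    matrix: dict[str, dict[str, float]] = {}
    for (receptor, hormone), _ in df.groupby(["receptor", "hormone"]):
        ds = DoseResponseDataset.from_table(df, receptor, hormone)
        fit = fit_hill(ds, fix_slope=fix_slope)
        matrix.setdefault(receptor, {})[hormone] = fit.logec50
        fits[(receptor, hormone)] = fit
    ref = c.get("reference")
    hormone = c.get("hormone") or sorted({h for _, h in fits})[0]
    per_h = {r: f for (r, h), f in fits.items() if h == hormone}
    if ref and ref in per_h:
        tab = sensitivity_table(per_h, ref)
    else:
        tab = pd.DataFrame(
            [{"receptor": r, "logEC50": f.logec50, "SE": f.se_logec50}
             for r, f in per_h.items()]
        )
    tab.to_csv(outputs[0], sep="\t", index=False, float_format="%.4f")
    pd.DataFrame(matrix).T.to_csv(outputs[1], sep="\t", float_format="%.4f")
    return outputs


def _run_regress(cfg: dict, out: Path, dry: bool) -> list[Path]:
    c = cfg["regress"]
    outputs = [out / "regression.json", out / "ddg_histogram.tsv"]
    if dry:
        return outputs
    ddg = read_table(c["ddg"], "ddg")
    ec50 = read_table(c["ec50"], "ec50")
    exclusions = {m: "configured exclusion" for m in c.get("exclude", [])}
    records = summarize_runs(ddg, exclusions)
    ec50_map = dict(zip(ec50["mutant"], ec50["logEC50"]))
    points = {
        r.mutant: (r.mean, float(ec50_map[r.mutant]))
        for r in records
        if not r.excluded and r.mutant in ec50_map
    }
    substr = c.get("exclude_containing", "")
    contrast = {m for m in points if substr and substr in m}
    anchor = bool(c.get("anchor", False))
    log.warning("regression anchor mode: %s", "through reference" if anchor else "plain OLS")
    full, reduced = regression_with_and_without(points, contrast, anchor=anchor)
    payload = {
        "n_points": full.n,
        "anchored": anchor,
        "full": {"slope": full.slope, "intercept": full.intercept,
                 "r_squared": full.r_squared},
        "excluding": sorted(contrast),
        "reduced": {"slope": reduced.slope, "intercept": reduced.intercept,
                    "r_squared": reduced.r_squared, "n": reduced.n},
    }
    outputs[0].write_text(json.dumps(payload, indent=2, sort_keys=True))
    hist = ddg_histogram(records, float(c.get("bin_width", 0.5)))
    hist.to_csv(outputs[1], sep="\t", index=False)
    return outputs
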
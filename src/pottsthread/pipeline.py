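"""End-to-end analysis pipeline: threading scores -> selectivity statistics.

A run is described by a flat key=value config file.  Required keys::

    msa=<fasta>            aligned kinase sequences
    model=<potts file>     serialized Potts model (with .json sidecar)
    dmap=<matrix file>     default contact-difference map
    panel=<csv>            long-form binding panel
    outdir=<dir>           output directory

Optional keys: ``dmap.<LABEL>=<file>`` for class-specific maps together with
``classes=<csv>`` (columns kinase_id, class_label); ``gatekeepers=<csv>``
(columns kinase_id, gatekeeper); and the numeric parameters listed in
``DEFAULT_PARAMS``.  Outputs (threading CSV, hit-rate CSV, ROC JSON per
selectivity threshold, randomization JSON, binned tables) embed the fully
resolved configuration and are byte-identical across runs of the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pottsthread import __version__
from pottsthread.alignment import read_alignment
from pottsthread.contacts import read_difference_map
from pottsthread.panel import (
    bin_by_score,
    binned_affinity_distribution,
    hit_rates,
    label_selectivity,
    read_panel_csv,
    roc_auc,
    subset_randomization,
)
from pottsthread.potts import load_model
from pottsthread.threadscore import results_to_frame, score_panel

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "kd_cutoff_nM": 10000.0,
    "selectivity_thresholds": "5,10,15",
    "rand_k": 16,
    "rand_iters": 10000,
    "rand_ceilings": "2,3,4",
    "seed": 0,
    "group_size": 25,
    "bin_size": 35,
    "upper_cutoff": 6.0,
    "lower_cutoff": 2.0,
    "gatekeeper_offset": 1.0,
}

_REQUIRED = ("msa", "model", "dmap", "panel", "outdir")


@dataclass
class RunConfig:
    """Resolved pipeline configuration (paths + parameters)."""

    paths: dict
    params: dict
    class_dmaps: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")
        missing = [k for k in _REQUIRED if k not in raw]
        if missing:
            raise ValueError(f"config lacks required key(s): {', '.join(missing)}")
        paths = {k: str((base / raw[k])) for k in _REQUIRED}
        for opt in ("classes", "gatekeepers"):
            if opt in raw:
                paths[opt] = str(base / raw[opt])
        class_dmaps = {
            k.split(".", 1)[1]: str(base / v)
            for k, v in raw.items() if k.startswith("dmap.")
        }
        params = dict(DEFAULT_PARAMS)
        for k, v in raw.items():
            if k in params:
                params[k] = type(DEFAULT_PARAMS[k])(v)
        return cls(paths=paths, params=params, class_dmaps=class_dmaps)

    def resolved(self) -> dict:
        return {
            "version": __version__,
            "paths": self.paths,
            "class_dmaps": self.class_dmaps,
            "params": self.params,
        }


def _int_list(spec: str) -> list[int]:
    return [int(x) for x in str(spec).split(",") if str(x).strip()]


def _read_two_column_csv(path, value_col: str) -> dict:
    df = pd.read_csv(path)
    if "kinase_id" not in df.columns or value_col not in df.columns:
        raise ValueError(f"{path}: need columns kinase_id, {value_col}")
    return dict(zip(df["kinase_id"], df[value_col]))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result tables and writes them.

    Partial outputs are removed if any stage fails.
    """
    outdir = Path(config.paths["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    def emit_json(obj, name: str) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
        written.append(p)

    try:
        return _run(config, emit_csv, emit_json)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, emit_csv, emit_json) -> dict:
    p = config.params
    aln = read_alignment(config.paths["msa"])
    model = load_model(config.paths["model"])
    panel = read_panel_csv(config.paths["panel"])
    default_dmap = read_difference_map(config.paths["dmap"])
    logger.info(
        "pipeline: %d kinases, %d inhibitors, L=%d, seed=%d",
        aln.n, len(panel.inhibitors), aln.L, p["seed"],
    )

    class_of = {}
    if "classes" in config.paths:
        class_of = _read_two_column_csv(config.paths["classes"], "class_label")
    maps = {lbl: read_difference_map(f) for lbl, f in config.class_dmaps.items()}
    assignment = {
        k: maps.get(class_of.get(k), default_dmap) for k in aln.ids
    }
    gatekeepers = {}
    if "gatekeepers" in config.paths:
        gatekeepers = _read_two_column_csv(config.paths["gatekeepers"], "gatekeeper")

    results = score_panel(
        model, aln, assignment, gatekeepers,
        gatekeeper_offset=p["gatekeeper_offset"],
        upper=p["upper_cutoff"], lower=p["lower_cutoff"],
    )
    tframe = results_to_frame(results)
    emit_csv(tframe, "threading.csv")
    scores = tframe.set_index("kinase_id")["adjusted_score"]

    rates = hit_rates(panel, kd_cutoff_nM=p["kd_cutoff_nM"])
    rates = rates.reindex(scores.index)
    if rates.isna().any():
        missing = list(rates.index[rates.isna()])
        raise ValueError(f"panel lacks kinase(s) present in the MSA: {missing}")
    emit_csv(
        rates.rename("hit_rate").reset_index().rename(columns={"index": "kinase_id"}),
        "hit_rates.csv",
    )

    roc_blocks = {}
    for thr in _int_list(p["selectivity_thresholds"]):
        labels = label_selectivity(rates, thr)
        if labels.nunique() < 2:
            logger.warning(
                "selectivity threshold %d yields a single class; no ROC", thr
            )
            roc_blocks[str(thr)] = {
                "selectivity_threshold": thr, "auc": None, "degenerate": True,
            }
            continue
        roc = roc_auc(scores, labels)
        roc_blocks[str(thr)] = {
            "selectivity_threshold": thr,
            "auc": roc.auc,
            "best_cutoff": roc.best_cutoff,
            "fpr": roc.fpr.tolist(),
            "tpr": roc.tpr.tolist(),
        }
    emit_json({"config": config.resolved(), "roc": roc_blocks}, "roc.json")

    rand = subset_randomization(
        panel, k=p["rand_k"], iterations=p["rand_iters"],
        hit_rate_ceilings=_int_list(p["rand_ceilings"]),
        seed=p["seed"], kd_cutoff_nM=p["kd_cutoff_nM"],
    )
    emit_json(
        {"config": config.resolved(),
         "randomization": rand.to_dict(orient="records")},
        "randomization.json",
    )

    emit_csv(bin_by_score(scores, rates, p["group_size"]), "bins_hitrate.csv")
    emit_csv(
        binned_affinity_distribution(panel, scores, bin_size=p["bin_size"]),
        "bins_affinity.csv",
    )
    return {
        "threading": tframe,
        "hit_rates": rates,
        "roc": roc_blocks,
        "randomization": rand,
    }
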
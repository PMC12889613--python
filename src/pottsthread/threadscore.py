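"""Threading scores: sequence-specific conformational reorganization penalties.

The threading score of a sequence S against a contact-difference map
delta_c = c_out - c_in is

    delta_T(S) = - sum_{i<j} J_ij(S_i, S_j) * delta_c_ij,

the negative Potts coupling energy contracted against the change in contact
frequencies between the active (DFG-in) and classical inactive (DFG-out)
ensembles.  A large delta_T means the couplings favored by this sequence are
the ones lost on reorganization: the predicted free-energy cost of reaching
the type II inhibitor-binding conformation is high, so the kinase is expected
to be selective against type II inhibitors.  delta_T is evaluated in the
zero-sum gauge, where per-pair coupling magnitudes are comparable; the score
is not gauge-invariant in general, so the gauge is fixed here once and
recorded.

Classification cutoffs follow the blind-test convention: delta_T above the
upper cutoff (default 6) predicts a selective kinase, below the lower cutoff
(default 2) a promiscuous one, in between indeterminate.  A large gatekeeper
residue restricts access to the type II pocket, which we fold in as a
configurable additive offset on the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pottsthread.alignment import Alignment
from pottsthread.contacts import ContactDifferenceMap
from pottsthread.potts import PottsModel, ZERO_SUM, _check_seqs, zero_sum_gauge

SELECTIVE = "selective"
PROMISCUOUS = "promiscuous"
INDETERMINATE = "indeterminate"

GATEKEEPER_LARGE = "large"
GATEKEEPER_SMALL = "small"
GATEKEEPER_UNKNOWN = "unknown"

DEFAULT_UPPER_CUTOFF = 6.0
DEFAULT_LOWER_CUTOFF = 2.0
DEFAULT_GATEKEEPER_OFFSET = 1.0


@dataclass
class ThreadingResult:
    kinase_id: str
    delta_T: float
    class_label: str
    gatekeeper: str = GATEKEEPER_UNKNOWN
    adjusted_score: float = None
    prediction: str = INDETERMINATE
    upper_cutoff: float = DEFAULT_UPPER_CUTOFF
    lower_cutoff: float = DEFAULT_LOWER_CUTOFF

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_T):
            raise ValueError(f"delta_T for {self.kinase_id!r} is not finite")
        if self.gatekeeper not in (GATEKEEPER_LARGE, GATEKEEPER_SMALL, GATEKEEPER_UNKNOWN):
            raise ValueError(f"unknown gatekeeper flag {self.gatekeeper!r}")
        if self.adjusted_score is None:
            self.adjusted_score = self.delta_T


def threading_score(
    model: PottsModel, seq: np.ndarray, dmap: ContactDifferenceMap
) -> float:
    """delta_T(S) = -sum_{i<j} J_ij(S_i, S_j) * delta_c_ij, in zero-sum gauge."""
    if model.L != dmap.L:
        raise ValueError(f"model L = {model.L} but difference map L = {dmap.L}")
    seqs = _check_seqs(np.asarray(seq), model.L, model.q)
    if model.gauge != ZERO_SUM:
        model = zero_sum_gauge(model)
    iu, ju = np.triu_indices(model.L, k=1)
    terms = model.J[iu, ju, seqs[:, iu], seqs[:, ju]] * dmap.delta[iu, ju]
    out = -terms.sum(axis=1)
    return float(out[0]) if out.shape[0] == 1 else out


def classify_kinase(
    res: ThreadingResult,
    upper: float = DEFAULT_UPPER_CUTOFF,
    lower: float = DEFAULT_LOWER_CUTOFF,
) -> str:
    """Selective / promiscuous / indeterminate from the adjusted score.

    The gatekeeper adjustment is already folded into ``adjusted_score`` (a
    large gatekeeper raises it), so a large gatekeeper can veto a borderline
    promiscuous call.
    """
    if not upper > lower:
        raise ValueError("upper cutoff must exceed lower cutoff")
    s = res.adjusted_score
    if s > upper:
        return SELECTIVE
    if s < lower:
        return PROMISCUOUS
    return INDETERMINATE


def score_panel(
    model: PottsModel,
    aln: Alignment,
    dmap_assignment: dict,
    gatekeepers: dict | None = None,
    gatekeeper_offset: float = DEFAULT_GATEKEEPER_OFFSET,
    upper: float = DEFAULT_UPPER_CUTOFF,
    lower: float = DEFAULT_LOWER_CUTOFF,
) -> list[ThreadingResult]:
    """Score every kinase in the alignment against its assigned difference map.

    ``dmap_assignment`` maps kinase_id -> ContactDifferenceMap (class-specific
    maps; e.g. kinases of the CMGC and STE families get the map built from
    their own families' ensembles).  ``gatekeepers`` maps kinase_id -> flag;
    adjusted_score = delta_T + gatekeeper_offset when the gatekeeper is large.
    Setting ``gatekeeper_offset=0`` gives the pure-threading ablation.
    """
    gatekeepers = gatekeepers or {}
    missing = [k for k in aln.ids if k not in dmap_assignment]
    if missing:
        raise ValueError(f"no difference-map assignment for kinase(s): {', '.join(missing)}")
    if model.gauge != ZERO_SUM:
        model = zero_sum_gauge(model)
    results = []
    for idx, kinase in enumerate(aln.ids):
        dmap = dmap_assignment[kinase]
        dt = threading_score(model, aln.seqs[idx], dmap)
        gk = gatekeepers.get(kinase, GATEKEEPER_UNKNOWN)
        adj = dt + (gatekeeper_offset if gk == GATEKEEPER_LARGE else 0.0)
        res = ThreadingResult(
            kinase_id=kinase, delta_T=dt, class_label=dmap.class_label,
            gatekeeper=gk, adjusted_score=adj,
            upper_cutoff=upper, lower_cutoff=lower,
        )
        res.prediction = classify_kinase(res, upper, lower)
        results.append(res)
    return results


def results_to_frame(results: list[ThreadingResult]) -> pd.DataFrame:
    """Tabulate threading results (one row per kinase)."""
    return pd.DataFrame(
        {
            "kinase_id": [r.kinase_id for r in results],
            "class_label": [r.class_label for r in results],
            "delta_T": [r.delta_T for r in results],
            "gatekeeper": [r.gatekeeper for r in results],
            "adjusted_score": [r.adjusted_score for r in results],
            "prediction": [r.prediction for r in results],
        }
    )
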
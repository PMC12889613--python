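"""Synthetic worlds with the statistical structure the analysis assumes.

A world consists of (i) a known sparse Potts model, (ii) kinase sequences
Gibbs-sampled from it, (iii) two toy structural ensembles whose contact
difference is +1 exactly on a controlled set of "flip" pairs, realizing an
active -> inactive reorganization, and (iv) a binding panel generated from
the free-energy decomposition

    dG_exp = dG_bind + dG_reorg,      dG_reorg = reorg_scale * dT + noise,

with Kd[nM] = 1e9 * exp(dG_exp / RT), RT = 0.593 kcal/mol (298 K, 1 M
standard state), censored at the assay ceiling.  Because the ground truth
(model parameters, flip pairs, per-kinase reorganization energies, per-pair
binding energies) is retained, every downstream stage — threading, hit
rates, randomization, ROC — can be tested against construction.

The geometry is deliberately schematic: residues sit far apart on a line so
that no incidental contacts exist, and the inactive ensemble adds one
pocket atom per flip pair.  Nothing about real kinase structure is emulated
beyond what the contact-map machinery needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pottsthread.alignment import Alignment, write_alignment
from pottsthread.contacts import (
    ACTIVE_IN,
    CLASSICAL_OUT,
    ContactDifferenceMap,
    StructureRecord,
    compute_contact_map,
    contact_difference,
    ensemble_frequency_pair,
    write_structure_pdb,
)
from pottsthread.panel import BindingPanel, panel_to_long, write_panel_csv
from pottsthread.potts import PottsModel, sample_sequences, zero_sum_gauge
from pottsthread.threadscore import (
    GATEKEEPER_LARGE,
    GATEKEEPER_SMALL,
    GATEKEEPER_UNKNOWN,
    score_panel,
)

RT_KCAL_MOL = 0.593
#: 1 M reference concentration expressed in nM: Kd[nM] = 1e9 * exp(dG/RT)
REFERENCE_CONC_NM = 1e9

_SPACING = 20.0    # A between consecutive residues of the toy chain
_POCKET = 4.0      # A from a flip partner to the added pocket atom
_JITTER = 0.4      # per-coordinate uniform jitter; margins keep contacts stable

_DIRS = np.array([
    [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0],
    [0.0, 0.0, -1.0], [0.0, 0.7071, 0.7071], [0.0, -0.7071, 0.7071],
])


@dataclass
class SyntheticWorld:
    """A fully known ground-truth world; see module docstring."""

    model: PottsModel
    alignment: Alignment
    in_structures: list[StructureRecord]
    out_structures: list[StructureRecord]
    dmap: ContactDifferenceMap
    class_labels: dict[str, str]
    gatekeepers: dict[str, str]
    flip_pairs: list[tuple[int, int]]
    true_delta_T: pd.Series
    true_reorg: pd.Series
    true_bind: np.ndarray
    true_dG_exp: np.ndarray
    panel: BindingPanel
    config: dict

    @property
    def kinases(self) -> list[str]:
        return list(self.alignment.ids)

    def save(self, outdir) -> None:
        """Emit the world as plain files: FASTA, PDBs + column maps, panel CSV,
        truth tables, and the generating config for exact replay."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, outdir / "kinases.fasta")
        write_panel_csv(self.panel, outdir / "panel.csv")
        struct_dir = outdir / "structures"
        struct_dir.mkdir(exist_ok=True)
        for rec in self.in_structures + self.out_structures:
            write_structure_pdb(rec, struct_dir / f"{rec.id}.pdb")
        L = self.alignment.L
        with open(struct_dir / "column_map.txt", "w") as fh:
            fh.write("# residue_number alignment_column\n")
            for i in range(L):
                fh.write(f"{i + 1} {i}\n")
        truth = pd.DataFrame(
            {
                "kinase_id": self.kinases,
                "true_delta_T": self.true_delta_T.to_numpy(),
                "true_dG_reorg": self.true_reorg.to_numpy(),
                "gatekeeper": [self.gatekeepers[k] for k in self.kinases],
                "class_label": [self.class_labels[k] for k in self.kinases],
            }
        )
        truth.to_csv(outdir / "truth_kinases.csv", index=False)
        pairs = panel_to_long(self.panel)
        dG = pd.DataFrame(
            self.true_dG_exp, index=self.kinases, columns=self.panel.inhibitors
        ).stack().rename("true_dG_exp").reset_index()
        dG.columns = ["kinase_id", "inhibitor_id", "true_dG_exp"]
        pairs.merge(dG, on=["kinase_id", "inhibitor_id"]).to_csv(
            outdir / "truth_pairs.csv", index=False
        )
        with open(outdir / "config.json", "w") as fh:
            json.dump(self.config, fh, indent=2, sort_keys=True)


def make_toy_structures(
    L: int,
    n_per_state: int,
    flip_pairs: list[tuple[int, int]],
    seed: int = 0,
    kinase_ids_in: list[str] | None = None,
    kinase_ids_out: list[str] | None = None,
    class_label: str = "SYN",
) -> tuple[list[StructureRecord], list[StructureRecord]]:
    """Two structure ensembles differing exactly on ``flip_pairs``.

    Residues are single carbon atoms spaced 20 A apart on a line, so no pair
    is in contact at the 6 A cutoff.  In the inactive ("out") ensemble each
    flip pair (i, j) gains a pocket atom on residue i placed 4 A from residue
    j, creating exactly that contact; per-structure jitter (< 0.4 A per
    coordinate) leaves every contact decision unchanged.  Flip pairs must be
    vertex-disjoint so added atoms cannot create incidental contacts.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    seen: set[int] = set()
    for (i, j) in flip_pairs:
        if not (0 <= i < L and 0 <= j < L and i != j):
            raise ValueError(f"flip pair ({i}, {j}) outside range for L = {L}")
        if i in seen or j in seen:
            raise ValueError("flip pairs must be vertex-disjoint")
        seen.update((i, j))
    rng = np.random.default_rng(seed)
    base = np.zeros((L, 3))
    base[:, 0] = _SPACING * np.arange(L)
    if kinase_ids_in is None:
        kinase_ids_in = [f"template_in_{n}" for n in range(n_per_state)]
    if kinase_ids_out is None:
        kinase_ids_out = [f"template_out_{n}" for n in range(n_per_state)]
    if len(kinase_ids_in) != n_per_state or len(kinase_ids_out) != n_per_state:
        raise ValueError("need one kinase id per structure in each ensemble")

    def build(n_idx: int, state: str, kid: str) -> StructureRecord:
        jit = rng.uniform(-_JITTER, _JITTER, size=(L, 3))
        coords = [np.atleast_2d(base[i] + jit[i]) for i in range(L)]
        if state == CLASSICAL_OUT:
            for p, (i, j) in enumerate(flip_pairs):
                pocket = base[j] + jit[j] + _POCKET * _DIRS[p % len(_DIRS)]
                coords[i] = np.vstack([coords[i], pocket])
        return StructureRecord(
            id=f"{state}_{n_idx}", kinase_id=kid, conformation=state,
            class_label=class_label, coords=coords,
        )

    ins = [build(n, ACTIVE_IN, kinase_ids_in[n]) for n in range(n_per_state)]
    outs = [build(n, CLASSICAL_OUT, kinase_ids_out[n]) for n in range(n_per_state)]
    return ins, outs


def _random_sparse_model(
    L: int, q: int, coupling_density: float, coupling_sd: float,
    field_sd: float, rng: np.random.Generator,
) -> tuple[PottsModel, list[tuple[int, int]]]:
    iu, ju = np.triu_indices(L, k=1)
    n_pairs = iu.size
    n_active = max(1, int(round(coupling_density * n_pairs)))
    pick = rng.choice(n_pairs, size=n_active, replace=False)
    J = np.zeros((L, L, q, q))
    for p in pick:
        i, j = int(iu[p]), int(ju[p])
        block = rng.normal(0.0, coupling_sd, size=(q, q))
        J[i, j] = block
        J[j, i] = block.T
    h = rng.normal(0.0, field_sd, size=(L, q))
    model = zero_sum_gauge(PottsModel(h=h, J=J, gauge="raw"))
    active = [(int(iu[p]), int(ju[p])) for p in sorted(pick)]
    return model, active


def _choose_flip_pairs(
    active: list[tuple[int, int]], n_flip: int, min_sep: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    # vertex-disjoint, well-separated pairs drawn preferentially from the
    # coupled pairs so the threading signal is nonzero
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    order = rng.permutation(len(active))
    for idx in order:
        i, j = active[idx]
        if j - i < min_sep or i in used or j in used:
            continue
        chosen.append((i, j))
        used.update((i, j))
        if len(chosen) == n_flip:
            return chosen
    raise ValueError(
        f"could only place {len(chosen)} of {n_flip} flip pairs; "
        "increase L or coupling_density"
    )


def make_world(
    L: int = 40,
    q: int = 8,
    n_kinases: int = 348,
    n_inhibitors: int = 50,
    coupling_density: float = 0.15,
    reorg_scale: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_flip_pairs: int | None = None,
    n_structures_per_state: int = 3,
    coupling_sd: float = 0.6,
    field_sd: float = 0.5,
    bind_mean_range: tuple[float, float] = (-10.5, -3.0),
    bind_sd: float = 1.0,
    censor_nM: float = 10000.0,
    burn_in: int = 200,
) -> SyntheticWorld:
    """Generate a complete ground-truth world; see module docstring.

    Parameters mirror the study's shape where it has one: 348 kinases and a
    50-inhibitor panel whose first 16 inhibitors carry the 'davis' tag and the
    rest 'schrodinger', a 10 uM censoring ceiling, and class-labelled
    conformational ensembles.  ``reorg_scale`` (kcal/mol per threading-score
    unit) and ``noise_sd`` (kcal/mol) control how faithfully the reorganization
    penalty follows the threading score; ``reorg_scale = 0`` gives the null
    world in which selectivity is unrelated to threading.
    """
    if L < 3 or q < 2 or n_kinases < 4 or n_inhibitors < 2:
        raise ValueError("need L >= 3, q >= 2, n_kinases >= 4, n_inhibitors >= 2")
    if not 0 < coupling_density <= 1:
        raise ValueError("coupling_density must be in (0, 1]")
    if noise_sd < 0 or bind_sd < 0:
        raise ValueError("noise scales must be non-negative")
    if n_flip_pairs is None:
        # vertex-disjoint pairs need room: cap at a quarter of the columns
        n_flip_pairs = max(2, min(10, L // 4))
    config = {
        "L": L, "q": q, "n_kinases": n_kinases, "n_inhibitors": n_inhibitors,
        "coupling_density": coupling_density, "reorg_scale": reorg_scale,
        "noise_sd": noise_sd, "seed": seed, "n_flip_pairs": n_flip_pairs,
        "n_structures_per_state": n_structures_per_state,
        "coupling_sd": coupling_sd, "field_sd": field_sd,
        "bind_mean_range": list(bind_mean_range), "bind_sd": bind_sd,
        "censor_nM": censor_nM, "burn_in": burn_in,
    }
    rng = np.random.default_rng(seed)

    model, active_pairs = _random_sparse_model(
        L, q, coupling_density, coupling_sd, field_sd, rng
    )
    flip_pairs = _choose_flip_pairs(active_pairs, n_flip_pairs, min_sep=3, rng=rng)

    aln = sample_sequences(
        model, n_kinases, burn_in=burn_in, thin=0,
        seed=int(rng.integers(2**31)),
    )
    aln = Alignment(
        aln.seqs, [f"kin_{k:04d}" for k in range(n_kinases)], aln.alphabet
    )

    ins, outs = make_toy_structures(
        L, n_structures_per_state, flip_pairs, seed=int(rng.integers(2**31))
    )
    in_maps = [compute_contact_map(r) for r in ins]
    out_maps = [compute_contact_map(r) for r in outs]
    c_in, c_out = ensemble_frequency_pair(
        in_maps, [r.kinase_id for r in ins],
        out_maps, [r.kinase_id for r in outs],
    )
    dmap = contact_difference(c_in, c_out, class_label="SYN")

    class_labels = {k: "SYN" for k in aln.ids}
    gk_draw = rng.random(n_kinases)
    gatekeepers = {
        k: (GATEKEEPER_LARGE if u < 0.3 else GATEKEEPER_SMALL if u < 0.8
            else GATEKEEPER_UNKNOWN)
        for k, u in zip(aln.ids, gk_draw)
    }

    results = score_panel(
        model, aln, {k: dmap for k in aln.ids}, gatekeepers, gatekeeper_offset=0.0
    )
    delta_T = pd.Series(
        [r.delta_T for r in results], index=aln.ids, name="true_delta_T"
    )
    reorg = reorg_scale * delta_T + rng.normal(0.0, noise_sd, size=n_kinases) \
        if noise_sd > 0 else reorg_scale * delta_T
    reorg = pd.Series(np.asarray(reorg), index=aln.ids, name="true_dG_reorg")

    lo, hi = bind_mean_range
    inh_means = rng.uniform(lo, hi, size=n_inhibitors)
    bind = inh_means[None, :] + (
        rng.normal(0.0, bind_sd, size=(n_kinases, n_inhibitors))
        if bind_sd > 0 else 0.0
    )
    dG_exp = bind + reorg.to_numpy()[:, None]
    kd_true = REFERENCE_CONC_NM * np.exp(dG_exp / RT_KCAL_MOL)
    censored = kd_true >= censor_nM
    kd = np.where(censored, censor_nM, kd_true)

    n_davis = 16 if n_inhibitors > 16 else max(1, n_inhibitors // 3)
    inhibitors = [f"inh_{m:03d}" for m in range(n_inhibitors)]
    datasets = ["davis"] * n_davis + ["schrodinger"] * (n_inhibitors - n_davis)
    panel = BindingPanel(
        kinases=list(aln.ids), inhibitors=inhibitors, datasets=datasets,
        kd=kd, censored=censored, censor_value=censor_nM,
    )

    return SyntheticWorld(
        model=model, alignment=aln, in_structures=ins, out_structures=outs,
        dmap=dmap, class_labels=class_labels, gatekeepers=gatekeepers,
        flip_pairs=flip_pairs, true_delta_T=delta_T, true_reorg=reorg,
        true_bind=bind, true_dG_exp=dG_exp, panel=panel, config=config,
    )


def load_world(path) -> SyntheticWorld:
    """Replay a saved world bit-identically from its stored config."""
    with open(Path(path) / "config.json") as fh:
        config = json.load(fh)
    config["bind_mean_range"] = tuple(config["bind_mean_range"])
    return make_world(**config)
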
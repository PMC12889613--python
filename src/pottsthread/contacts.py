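"""Contact maps and conformational contact-frequency ensembles.

Each kinase conformational state (active DFG-in vs classical DFG-out) is
summarized by a contact-frequency map: the redundancy-weighted average of
binary residue-residue contact matrices over an ensemble of structures.  Two
residues are in contact when their minimum heavy-atom distance is strictly
below a cutoff (default 6 A).  Structures of the same kinase are down-weighted
by w_n = 1/u_n, where u_n counts how many structures of that kinase appear in
the ensemble pair, so that kinases overrepresented in the PDB do not dominate
the average.  The difference map delta_c = c_out - c_in of a kinase class is
the object the threading score contracts against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

ACTIVE_IN = "active_in"
CLASSICAL_OUT = "classical_out"
CONFORMATIONS = (ACTIVE_IN, CLASSICAL_OUT)

DEFAULT_CUTOFF = 6.0
#: contacts closer than this many alignment columns along the chain are
#: dropped: backbone-adjacent contacts are conformation-independent noise.
DEFAULT_MIN_SEPARATION = 3


@dataclass
class StructureRecord:
    """One structure: per-alignment-column heavy-atom coordinates.

    ``coords[i]`` is an (n_atoms, 3) array for the residue aligned to column
    i, or None when the column is unresolved / unaligned in this structure.
    """

    id: str
    kinase_id: str
    conformation: str
    class_label: str
    coords: list

    def __post_init__(self) -> None:
        if self.conformation not in CONFORMATIONS:
            raise ValueError(
                f"conformation must be one of {CONFORMATIONS}, got {self.conformation!r}"
            )
        n_resolved = sum(c is not None for c in self.coords)
        if n_resolved < 2:
            raise ValueError(
                f"structure {self.id!r} resolves {n_resolved} position(s); need >= 2"
            )

    @property
    def L(self) -> int:
        return len(self.coords)

    @property
    def mask(self) -> np.ndarray:
        """True where the alignment column has no coordinates."""
        return np.array([c is None for c in self.coords])


@dataclass
class ContactMap:
    """Binary symmetric contact matrix with a mask for coordinate-free columns."""

    contacts: np.ndarray
    mask: np.ndarray
    kinase_id: str = ""
    conformation: str = ""

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        L = self.contacts.shape[0]
        if self.contacts.shape != (L, L):
            raise ValueError("contacts must be square")
        if self.mask.shape != (L,):
            raise ValueError("mask must be length L")
        if not np.array_equal(self.contacts, self.contacts.T):
            raise ValueError("contacts must be symmetric")
        if np.abs(np.diag(self.contacts)).max(initial=0) != 0:
            raise ValueError("contacts must have a zero diagonal")
        if not np.isin(self.contacts, (0, 1)).all():
            raise ValueError("contacts must be binary")

    @property
    def L(self) -> int:
        return self.contacts.shape[0]


@dataclass
class ContactFrequencyMap:
    """Weighted mean contact frequencies for one conformational ensemble.

    ``freqs[i, j]`` is NaN where no structure in the ensemble resolves both
    columns; ``coverage`` holds the total weight behind each entry.
    """

    freqs: np.ndarray
    state: str
    n_structures: int
    weights: np.ndarray
    coverage: np.ndarray = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        L = self.freqs.shape[0]
        if self.freqs.shape != (L, L):
            raise ValueError("freqs must be square")
        finite = self.freqs[np.isfinite(self.freqs)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.state not in CONFORMATIONS:
            raise ValueError(f"state must be one of {CONFORMATIONS}")
        if self.coverage is None:
            self.coverage = np.where(np.isfinite(self.freqs), 1.0, 0.0)

    @property
    def L(self) -> int:
        return self.freqs.shape[0]


@dataclass
class ContactDifferenceMap:
    """delta = c_out - c_in for one kinase class; entries in [-1, 1].

    Pairs unobserved in either ensemble carry delta = 0 (no evidence of
    conformational change) and are flagged in ``observed``.
    """

    delta: np.ndarray
    class_label: str
    observed: np.ndarray = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        L = self.delta.shape[0]
        if self.delta.shape != (L, L):
            raise ValueError("delta must be square")
        if not np.allclose(self.delta, self.delta.T, atol=1e-9):
            raise ValueError("delta must be symmetric")
        if np.abs(self.delta).max(initial=0.0) > 1 + 1e-9:
            raise ValueError("delta entries must lie in [-1, 1]")
        if self.observed is None:
            self.observed = np.ones_like(self.delta, dtype=bool)

    @property
    def L(self) -> int:
        return self.delta.shape[0]


def compute_contact_map(
    rec: StructureRecord,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactMap:
    """Binary contacts: minimum heavy-atom distance strictly below ``cutoff``.

    Column pairs closer than ``min_separation`` along the alignment are set to
    zero; masked (unresolved) columns contribute no contacts and are flagged
    in the map's mask rather than silently reported as non-contacts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    L = rec.L
    contacts = np.zeros((L, L), dtype=np.int8)
    resolved = [i for i, c in enumerate(rec.coords) if c is not None]
    for a, i in enumerate(resolved):
        ci = np.atleast_2d(np.asarray(rec.coords[i], dtype=float))
        for j in resolved[a + 1:]:
            if j - i < min_separation:
                continue
            cj = np.atleast_2d(np.asarray(rec.coords[j], dtype=float))
            if cdist(ci, cj).min() < cutoff:
                contacts[i, j] = contacts[j, i] = 1
    return ContactMap(contacts, rec.mask, rec.kinase_id, rec.conformation)


def kinase_multiplicity(kinase_ids: list[str]) -> dict[str, int]:
    """u: occurrences of each kinase among the given structures."""
    counts: dict[str, int] = {}
    for k in kinase_ids:
        counts[k] = counts.get(k, 0) + 1
    return counts


def contact_frequency(
    maps: list[ContactMap],
    kinase_ids: list[str],
    state: str,
    multiplicity: dict[str, int] | None = None,
) -> ContactFrequencyMap:
    """Redundancy-weighted mean contact map, w_n = 1 / u(kinase_n).

    ``multiplicity`` supplies the kinase occurrence counts u; by default they
    are counted within ``maps`` alone, but the caller may pass counts taken
    over the union of both conformational ensembles (see
    :func:`ensemble_frequency_pair`).  Entries are averaged only over the
    structures that resolve both columns (per-entry effective weights), so
    flexible unresolved regions do not bias frequencies toward zero.
    """
    if not maps:
        raise ValueError("need at least one contact map")
    if len(kinase_ids) != len(maps):
        raise ValueError("one kinase id per map required")
    L = maps[0].L
    if any(m.L != L for m in maps):
        raise ValueError("all maps must share L")
    if multiplicity is None:
        multiplicity = kinase_multiplicity(kinase_ids)
    weights = np.array([1.0 / multiplicity[k] for k in kinase_ids])
    num = np.zeros((L, L))
    den = np.zeros((L, L))
    for w, m in zip(weights, maps):
        ok = ~m.mask
        valid = np.outer(ok, ok)
        num += w * valid * m.contacts
        den += w * valid
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(freqs, 0.0)
    return ContactFrequencyMap(
        freqs=freqs, state=state, n_structures=len(maps),
        weights=weights, coverage=den,
    )


def ensemble_frequency_pair(
    in_maps: list[ContactMap],
    in_ids: list[str],
    out_maps: list[ContactMap],
    out_ids: list[str],
    u_mode: str = "union",
) -> tuple[ContactFrequencyMap, ContactFrequencyMap]:
    """Frequency maps for an active/inactive ensemble pair.

    ``u_mode='union'`` (default) counts each kinase's occurrences across both
    ensembles when forming the 1/u weights; ``'within'`` counts within each
    ensemble separately.
    """
    if u_mode == "union":
        mult = kinase_multiplicity(in_ids + out_ids)
        m_in = m_out = mult
    elif u_mode == "within":
        m_in = kinase_multiplicity(in_ids)
        m_out = kinase_multiplicity(out_ids)
    else:
        raise ValueError("u_mode must be 'union' or 'within'")
    c_in = contact_frequency(in_maps, in_ids, ACTIVE_IN, m_in)
    c_out = contact_frequency(out_maps, out_ids, CLASSICAL_OUT, m_out)
    return c_in, c_out


def contact_difference(
    c_in: ContactFrequencyMap,
    c_out: ContactFrequencyMap,
    class_label: str,
) -> ContactDifferenceMap:
    """delta = c_out - c_in.  The sign convention is load-bearing: a positive
    entry is a contact gained on reorganizing to the inactive state."""
    if c_in.L != c_out.L:
        raise ValueError("frequency maps must share L")
    if c_in.state != ACTIVE_IN or c_out.state != CLASSICAL_OUT:
        raise ValueError(
            f"expected c_in.state={ACTIVE_IN!r} and c_out.state={CLASSICAL_OUT!r}; "
            f"got {c_in.state!r} / {c_out.state!r} (are the ensembles swapped?)"
        )
    observed = np.isfinite(c_in.freqs) & np.isfinite(c_out.freqs)
    delta = np.where(observed, c_out.freqs - c_in.freqs, 0.0)
    np.fill_diagonal(delta, 0.0)
    return ContactDifferenceMap(delta=delta, class_label=class_label, observed=observed)


# ---------------------------------------------------------------------------
# I/O: PDB coordinates and text serialization of maps

def read_column_map(path) -> dict[int, int]:
    """Two-column text map: structure residue number -> 0-based alignment column."""
    mapping: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'resnum column'")
            mapping[int(parts[0])] = int(parts[1])
    return mapping


def read_structure_pdb(
    path,
    L: int,
    column_map: dict[int, int],
    kinase_id: str,
    conformation: str,
    class_label: str = "",
    structure_id: str | None = None,
) -> StructureRecord:
    """Load heavy-atom coordinates from a PDB file, one residue per column."""
    st = gemmi.read_structure(str(path))
    coords: list = [None] * L
    model = st[0]
    for chain in model:
        for res in chain:
            col = column_map.get(res.seqid.num)
            if col is None:
                continue
            if not 0 <= col < L:
                raise ValueError(f"column {col} for residue {res.seqid.num} outside [0, {L})")
            xyz = [
                (a.pos.x, a.pos.y, a.pos.z)
                for a in res
                if a.element.name != "H"
            ]
            if xyz:
                coords[col] = np.asarray(xyz)
    return StructureRecord(
        id=structure_id or st.name or str(path),
        kinase_id=kinase_id,
        conformation=conformation,
        class_label=class_label,
        coords=coords,
    )


def write_structure_pdb(rec: StructureRecord, path) -> None:
    """Write a record's heavy atoms as a single-chain PDB file (carbon atoms)."""
    serial = 0
    with open(path, "w") as fh:
        for col, xyz in enumerate(rec.coords):
            if xyz is None:
                continue
            for k, (x, y, z) in enumerate(np.atleast_2d(xyz)):
                serial += 1
                name = f"C{k + 1}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} ALA A{col + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"           C\n"
                )
        fh.write("END\n")


def _write_matrix(path, matrix: np.ndarray, header: dict) -> None:
    items = " ".join(f"{k}={v}" for k, v in header.items())
    np.savetxt(path, matrix, fmt="%.10g", header=items)


def _read_matrix(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline()
    header = {}
    for token in first.lstrip("# ").split():
        if "=" in token:
            k, v = token.split("=", 1)
            header[k] = v
    return np.loadtxt(path), header


def write_frequency_map(fmap: ContactFrequencyMap, path) -> None:
    _write_matrix(path, fmap.freqs, {
        "kind": "contact_frequency", "L": fmap.L,
        "state": fmap.state, "n_structures": fmap.n_structures,
    })


def read_frequency_map(path) -> ContactFrequencyMap:
    m, h = _read_matrix(path)
    if h.get("kind") != "contact_frequency":
        raise ValueError(f"{path} is not a contact-frequency map")
    n = int(h.get("n_structures", 1))
    return ContactFrequencyMap(
        freqs=m, state=h["state"], n_structures=n, weights=np.ones(n),
    )


def write_difference_map(dmap: ContactDifferenceMap, path) -> None:
    _write_matrix(path, dmap.delta, {
        "kind": "contact_difference", "L": dmap.L, "class_label": dmap.class_label,
    })


def read_difference_map(path) -> ContactDifferenceMap:
    m, h = _read_matrix(path)
    if h.get("kind") != "contact_difference":
        raise ValueError(f"{path} is not a contact-difference map")
    return ContactDifferenceMap(delta=m, class_label=h.get("class_label", ""))
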
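"""Structure parsing and per-residue annotation.

Chains are read from PDB or mmCIF files with gemmi.  The full construct
sequence comes from the sequence records (SEQRES / entity_poly); residues
present in the construct but absent from the coordinate model are flagged
``rem465`` after the PDB remark that lists missing residues — a widely used
proxy for structural disorder.  Window extraction works in full-sequence
space so that missing residues still occupy their window slots; author
numbering is carried alongside for reporting.

Only the first model of multi-model files is used.  Alternate locations
resolve to the highest-occupancy conformer.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "ResidueEntry",
    "AnnotatedChain",
    "SiteWindow",
    "parse_chain",
    "eligible_chain",
    "standardise_bfactors",
    "extract_window",
    "write_chain_annotation",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class ResidueEntry:
    """One position of the construct sequence, observed or not."""

    seq_index: int                  # 1-based index into full_sequence
    author_number: str              # author residue number + insertion code
    aa: str                         # one-letter code, 'X' if unmappable
    observed: bool
    backbone: dict[str, np.ndarray] = field(default_factory=dict)
    cb: np.ndarray | None = None
    ca_bfactor: float | None = None

    @property
    def rem465(self) -> bool:
        return not self.observed

    def has_backbone(self, atoms=("N", "CA", "C")) -> bool:
        return self.observed and all(a in self.backbone for a in atoms)


@dataclass
class AnnotatedChain:
    pdb_id: str
    chain_id: str
    residues: list[ResidueEntry]
    resolution: float | None
    method: str
    full_sequence: str

    def __len__(self) -> int:
        return len(self.full_sequence)

    @property
    def n_observed(self) -> int:
        return sum(r.observed for r in self.residues)

    @property
    def n_missing(self) -> int:
        return sum(r.rem465 for r in self.residues)

    def residue_at(self, seq_index: int) -> ResidueEntry | None:
        if 1 <= seq_index <= len(self.residues):
            return self.residues[seq_index - 1]
        return None


@dataclass
class SiteWindow:
    """7-residue structural window centred on a candidate site.

    ``superposition_atoms`` holds the 8 atoms used for pairwise rigid-body
    superposition, in fixed order: Cα at offsets −3 … +3, then the central
    residue's Cβ.  They are defined only for backbone-complete windows.
    """

    chain_ref: tuple[str, str]
    center_seq_index: int
    window_entries: list[ResidueEntry | None]
    backbone_complete: bool
    superposition_atoms: np.ndarray | None = None

    @property
    def window_id(self) -> str:
        pdb, ch = self.chain_ref
        return f"{pdb}_{ch}_{self.center_seq_index}"

    @property
    def center_entry(self) -> ResidueEntry | None:
        return self.window_entries[3]


_ONE_LETTER_CACHE: dict[str, str] = {}


def _one_letter(resname: str) -> str:
    """Three-letter (incl. modified residues) to upper-case one-letter, 'X' if unknown."""
    if resname not in _ONE_LETTER_CACHE:
        info = gemmi.find_tabulated_residue(resname)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            _ONE_LETTER_CACHE[resname] = code if code.isalpha() else "X"
        else:
            _ONE_LETTER_CACHE[resname] = "X"
    return _ONE_LETTER_CACHE[resname]


def _best_atom(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Highest-occupancy atom with the given name (altloc resolution)."""
    best = None
    for atom in residue:
        if atom.name == name and (best is None or atom.occ > best.occ):
            best = atom
    return best


def parse_chain(structure_file: str | Path, chain_id: str) -> AnnotatedChain:
    """Read one chain of a PDB/mmCIF file into an :class:`AnnotatedChain`.

    The construct sequence is reconstructed from the sequence records; when a
    file has none, the observed residues alone define the sequence (with a
    warning, since missing-residue detection is then impossible).
    """
    st = gemmi.read_structure(str(structure_file))
    st.setup_entities()
    st.assign_label_seq_id()
    if len(st) == 0:
        raise ValueError(f"no models in {structure_file}")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found in {structure_file}")
    polymer = chain.get_polymer()
    entity = st.get_entity_of(polymer)

    if entity is not None and entity.full_sequence:
        seq_names = [gemmi.Entity.first_mon(m) for m in entity.full_sequence]
    else:
        warnings.warn(f"{structure_file}: no sequence records for chain "
                      f"{chain_id}; using observed residues only")
        seq_names = [res.name for res in polymer]

    full_sequence = "".join(_one_letter(n) for n in seq_names)
    entries = [ResidueEntry(seq_index=i + 1, author_number="", aa=aa,
                            observed=False)
               for i, aa in enumerate(full_sequence)]

    fallback_index = 0
    for res in polymer:
        label_seq = res.label_seq
        if label_seq is None or not (1 <= label_seq <= len(entries)):
            fallback_index += 1
            label_seq = fallback_index
            if label_seq > len(entries):
                continue
        entry = entries[label_seq - 1]
        entry.observed = True
        entry.author_number = f"{res.seqid.num}{res.seqid.icode}".strip()
        obs_aa = _one_letter(res.name)
        if entry.aa == "X" and obs_aa != "X":
            entry.aa = obs_aa
        for name in BACKBONE_ATOMS:
            atom = _best_atom(res, name)
            if atom is not None:
                entry.backbone[name] = np.array(atom.pos.tolist())
        cb = _best_atom(res, "CB")
        if cb is not None:
            entry.cb = np.array(cb.pos.tolist())
        ca = _best_atom(res, "CA")
        if ca is not None:
            entry.ca_bfactor = float(ca.b_iso)
        if ca is None:
            # observed residue without CA violates the entry invariant;
            # treat as unobserved
            entry.observed = False
            entry.backbone.clear()
            entry.cb = None

    resolution = float(st.resolution) if st.resolution > 0 else None
    method = (st.info["_exptl.method"]
              if "_exptl.method" in st.info else "")
    return AnnotatedChain(pdb_id=(st.name or "").lower()[:4] or "xxxx",
                          chain_id=chain_id, residues=entries,
                          resolution=resolution, method=method,
                          full_sequence=full_sequence)


def eligible_chain(c: AnnotatedChain, min_len: int = 31,
                   max_res: float = 2.50) -> bool:
    """X-ray chains longer than 30 residues solved to 2.5 Å or better."""
    if c.resolution is None:
        warnings.warn(f"{c.pdb_id}_{c.chain_id}: missing resolution; "
                      "chain not eligible")
        return False
    is_xray = "X-RAY" in c.method.upper()
    return is_xray and len(c) >= min_len and c.resolution <= max_res


def standardise_bfactors(c: AnnotatedChain) -> dict[int, float]:
    """Z-score Cα B-factors over all observed Cα of the same chain.

    Returns a map seq_index -> z.  Population standard deviation is used;
    a degenerate (zero-variance) chain gets all-zero scores with a warning.
    """
    pairs = [(r.seq_index, r.ca_bfactor) for r in c.residues
             if r.observed and r.ca_bfactor is not None]
    if len(pairs) < 2:
        raise ValueError("need at least 2 observed residues with B-factors")
    values = np.array([b for _, b in pairs])
    sd = values.std()  # population SD
    if sd == 0:
        warnings.warn(f"{c.pdb_id}_{c.chain_id}: zero B-factor variance; "
                      "all z-scores set to 0")
        return {i: 0.0 for i, _ in pairs}
    mean = values.mean()
    return {i: float((b - mean) / sd) for i, b in pairs}


def extract_window(c: AnnotatedChain, center_seq_index: int,
                   require_st: bool = True, require_cb: bool = True
                   ) -> SiteWindow | None:
    """Extract the ±3 window around a residue in full-sequence space.

    Returns ``None`` when ``require_st`` is set and the central residue is
    not serine/threonine (with a warning).  ``backbone_complete`` requires
    all 7 residues observed with N, CA, C and, when ``require_cb``, a Cβ on
    the central residue (so glycine-centred background windows are
    incomplete by definition).
    """
    center = c.residue_at(center_seq_index)
    if center is None:
        raise IndexError(f"seq index {center_seq_index} outside chain "
                         f"{c.pdb_id}_{c.chain_id}")
    if require_st and center.aa not in "ST":
        warnings.warn(f"{c.pdb_id}_{c.chain_id}:{center_seq_index} central "
                      f"residue {center.aa} is not S/T; window skipped")
        return None
    entries = [c.residue_at(center_seq_index + off) for off in range(-3, 4)]
    complete = all(e is not None and e.has_backbone() for e in entries)
    if complete and require_cb:
        complete = entries[3].cb is not None
    atoms = None
    if complete:
        cas = [e.backbone["CA"] for e in entries]
        stack = cas + [entries[3].cb] if require_cb else cas
        atoms = np.stack(stack)
    return SiteWindow(chain_ref=(c.pdb_id, c.chain_id),
                      center_seq_index=center_seq_index,
                      window_entries=entries, backbone_complete=complete,
                      superposition_atoms=atoms)


def write_chain_annotation(c: AnnotatedChain, path: str | Path) -> None:
    """Per-chain annotation CSV (positions are 1-based in sequence space)."""
    z = {}
    try:
        z = standardise_bfactors(c)
    except ValueError:
        pass
    with open(path, "w", newline="") as fh:
        fh.write("# positions are 1-based indices into the construct "
                 "sequence; B-factor z-scores use the population SD\n")
        writer = csv.writer(fh)
        writer.writerow(["seq_index", "author_number", "aa", "observed",
                         "rem465", "bfactor_z"])
        for r in c.residues:
            writer.writerow([r.seq_index, r.author_number, r.aa,
                             int(r.observed), int(r.rem465),
                             f"{z[r.seq_index]:.4f}" if r.seq_index in z else ""])
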
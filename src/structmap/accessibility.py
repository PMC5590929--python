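"""Secondary structure and relative solvent accessibility annotation.

Assignments come either from user-supplied DSSP output files (the package
never executes DSSP itself) or from built-in geometric fallbacks: a
Shrake–Rupley sphere-sampling accessible-surface calculation and a
dihedral-based 3-state secondary-structure assigner.  Outputs are labelled
with the assignment source.

The 8-state to 3-state reduction used throughout is: G,H → H; I,B,E → E;
everything else, including unassigned residues, → C.  Relative solvent
accessibility (RSA) is the residue's accessible area divided by its
residue-type maximum; S/T sites are binned as buried (RSA ≤ 5%), partially
buried (5% < RSA ≤ 25%) or exposed (RSA > 25%), both boundaries inclusive
on the buried side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import phi_psi_from_backbone
from .structure_model import AnnotatedChain

logger = logging.getLogger(__name__)

__all__ = [
    "SsRsaAnnotation",
    "MAX_ASA_TIEN", "MAX_ASA_MILLER",
    "parse_dssp", "reduce_ss8_to_ss3", "normalise_rsa", "bin_rsa",
    "shrake_rupley_asa", "dihedral_ss3",
]

# Theoretical maximum accessible surface areas (Å^2), Tien et al. 2013.
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Empirical tripeptide maxima, Miller et al. 1987.
MAX_ASA_MILLER = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}

MAX_ASA_SCALES = {"tien2013": MAX_ASA_TIEN, "miller1987": MAX_ASA_MILLER}

SS8_TOKENS = set("GHISTBE ")

_SS3_MAP = {"G": "H", "H": "H",
            "I": "E", "B": "E", "E": "E",
            "S": "C", "T": "C", " ": "C", "": "C", "blank": "C"}


@dataclass
class SsRsaAnnotation:
    ss8: str
    ss3: str
    asa: float
    rsa: float | None
    rsa_bin: str | None


def reduce_ss8_to_ss3(ss8: str) -> str:
    """8-state DSSP token to 3 states: G,H→H; I,B,E→E; S,T,blank→C."""
    if ss8 not in _SS3_MAP:
        raise ValueError(f"unknown secondary-structure token {ss8!r}")
    return _SS3_MAP[ss8]


def normalise_rsa(asa: float, aa: str, scale: str = "tien2013"
                  ) -> float | None:
    """ASA (Å²) divided by the residue-type maximum of the chosen scale.

    Values above 1 are possible with empirical scales and are kept.
    Returns None (with a warning) for residues absent from the table.
    """
    table = MAX_ASA_SCALES[scale]
    if aa not in table:
        warnings.warn(f"no maximum ASA for residue {aa!r}; RSA undefined")
        return None
    rsa = asa / table[aa]
    if rsa > 1.0:
        logger.debug("RSA %.2f > 1 for %s (asa %.1f)", rsa, aa, asa)
    return rsa


def bin_rsa(rsa: float) -> str:
    """Three-level burial class; both cut-offs are inclusive on the left."""
    if rsa < 0:
        raise ValueError("rsa must be >= 0")
    if rsa <= 0.05:
        return "buried"
    if rsa <= 0.25:
        return "partial"
    return "exposed"


def parse_dssp(path: str | Path) -> dict[tuple[str, str], tuple[str, float]]:
    """Read a classic-format DSSP file.

    Returns a map (chain_id, author_number) -> (ss8, asa).  Chain-break
    records ('!') are skipped; ss8 is ' ' for unassigned residues.
    """
    out: dict[tuple[str, str], tuple[str, float]] = {}
    with open(path) as fh:
        in_body = False
        for lineno, line in enumerate(fh, start=1):
            if not in_body:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_body = True
                continue
            if len(line.rstrip("\n")) < 38:
                raise ValueError(f"{path}: malformed DSSP record at line "
                                 f"{lineno}")
            aa = line[13]
            if aa == "!":
                continue
            chain = line[11]
            number = (line[5:10] + line[10]).strip()
            ss8 = line[16]
            if ss8 not in SS8_TOKENS:
                raise ValueError(f"{path}: unknown SS token {ss8!r} at line "
                                 f"{lineno}")
            try:
                asa = float(line[34:38])
            except ValueError as exc:
                raise ValueError(f"{path}: bad ACC field at line {lineno}"
                                 ) from exc
            out[(chain, number)] = (ss8, asa)
    if not in_body:
        raise ValueError(f"{path}: no DSSP data header found")
    return out


# van der Waals radii (Å) for the heavy atoms scored here
_VDW = {"N": 1.55, "C": 1.70, "O": 1.52, "S": 1.80}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_asa(chain: AnnotatedChain, probe: float = 1.4,
                      points: int = 960) -> dict[int, float]:
    """Per-residue accessible surface area by sphere-point sampling.

    Each heavy atom is covered with a deterministic quasi-uniform point set
    on its solvent-expanded sphere; points not occluded by any neighbouring
    atom contribute surface area.  Results are summed per residue and keyed
    by seq_index.  Residues without coordinates are skipped.
    """
    atoms = []          # (residue seq_index, element, xyz)
    for r in chain.residues:
        if not r.observed:
            continue
        for name, xyz in r.backbone.items():
            atoms.append((r.seq_index, name[0], xyz))
        if r.cb is not None:
            atoms.append((r.seq_index, "C", r.cb))
    if not atoms:
        return {}
    xyz = np.array([a[2] for a in atoms])
    radii = np.array([_VDW.get(a[1], 1.7) + probe for a in atoms])
    unit = _sphere_points(points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    asa: dict[int, float] = {}
    for i, (seq_index, _elem, _p) in enumerate(atoms):
        sphere = xyz[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                      if j != i]
        accessible = np.ones(points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((sphere - xyz[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
        asa[seq_index] = asa.get(seq_index, 0.0) + area
    return asa


# Dihedral windows (degrees) for the fallback 3-state assigner
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-180.0, -40.0)
_STRAND_PSI = (90.0, 180.0)


def _in(window: tuple[float, float], value: float) -> bool:
    return window[0] <= value <= window[1]


def dihedral_ss3(chain: AnnotatedChain) -> dict[int, str]:
    """Backbone-dihedral 3-state assignment (non-DSSP fallback).

    A residue is H (E) when its own phi/psi and both neighbours' fall in the
    helical (extended) region; everything else, including chain termini and
    residues around gaps, is C.  Keyed by seq_index for observed residues.
    """
    observed = [r for r in chain.residues if r.has_backbone()]
    # consecutive runs in sequence space; dihedrals need i-1, i, i+1
    seq_idx = {r.seq_index: r for r in observed}
    state: dict[int, str] = {}
    raw: dict[int, tuple[float, float]] = {}
    for r in observed:
        prev = seq_idx.get(r.seq_index - 1)
        nxt = seq_idx.get(r.seq_index + 1)
        if prev is None or nxt is None:
            continue
        N, CA, C = (np.stack([prev.backbone[a], r.backbone[a],
                              nxt.backbone[a]]) for a in ("N", "CA", "C"))
        pp = phi_psi_from_backbone(N, CA, C)
        raw[r.seq_index] = (pp[1, 0], pp[1, 1])
    for r in observed:
        angles = [raw.get(r.seq_index + d) for d in (-1, 0, 1)]
        if any(a is None for a in angles):
            state[r.seq_index] = "C"
        elif all(_in(_HELIX_PHI, a[0]) and _in(_HELIX_PSI, a[1])
                 for a in angles):
            state[r.seq_index] = "H"
        elif all(_in(_STRAND_PHI, a[0]) and _in(_STRAND_PSI, a[1])
                 for a in angles):
            state[r.seq_index] = "E"
        else:
            state[r.seq_index] = "C"
    return state


def annotate_chain(chain: AnnotatedChain,
                   dssp: dict[tuple[str, str], tuple[str, float]] | None = None,
                   scale: str = "tien2013",
                   probe: float = 1.4, points: int = 960
                   ) -> dict[int, SsRsaAnnotation]:
    """Full SS + RSA annotation, from DSSP records when given, else fallbacks.

    Keyed by seq_index.  With DSSP input, residues are matched on
    (chain_id, author_number); without, the Shrake–Rupley surface and
    dihedral assigner are used and ss8 is reported as the ss3 token.
    """
    out: dict[int, SsRsaAnnotation] = {}
    if dssp is not None:
        for r in chain.residues:
            if not r.observed:
                continue
            rec = dssp.get((chain.chain_id, r.author_number))
            if rec is None:
                continue
            ss8, asa = rec
            rsa = normalise_rsa(asa, r.aa, scale)
            out[r.seq_index] = SsRsaAnnotation(
                ss8=ss8, ss3=reduce_ss8_to_ss3(ss8), asa=asa, rsa=rsa,
                rsa_bin=bin_rsa(rsa) if rsa is not None else None)
        return out
    asa_map = shrake_rupley_asa(chain, probe=probe, points=points)
    ss3_map = dihedral_ss3(chain)
    for r in chain.residues:
        if r.seq_index not in asa_map:
            continue
        asa = asa_map[r.seq_index]
        rsa = normalise_rsa(asa, r.aa, scale)
        ss3 = ss3_map.get(r.seq_index, "C")
        out[r.seq_index] = SsRsaAnnotation(
            ss8=ss3, ss3=ss3, asa=asa, rsa=rsa,
            rsa_bin=bin_rsa(rsa) if rsa is not None else None)
    return out
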
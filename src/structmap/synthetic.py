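"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here: protein chains with
ideal-geometry backbones written as PDB files (with SEQRES records, planted
missing regions and lognormal B-factors), matching FASTA sequences, site
tables, residue-level mapping tables, DSSP-like annotation files and
per-residue disorder-score tracks with a planted enrichment around sites.
Each generator is deterministic given its seed, and truth tables record every
planted quantity so downstream stages can be scored without reference to
generator internals.

Synthetic structures use the reserved 4-character id namespace ``s001,
s002, …`` which never collides with real PDB codes (real codes start with
a digit).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import build_backbone

__all__ = [
    "SyntheticSpec",
    "PHI_PSI_STATES",
    "MOTIF_TEMPLATES",
    "generate_ideal_peptide",
    "generate_window_set",
    "generate_structure_set",
    "generate_disorder_tracks",
    "write_dssp_file",
]

# Backbone conformational states (phi, psi) in degrees used to compose
# synthetic chains: alpha helix, beta strand, left-handed helix, an extended
# glycine-like state, polyproline II and a bridge-like extended state.
PHI_PSI_STATES: dict[str, tuple[float, float]] = {
    "H": (-57.0, -47.0),
    "E": (-120.0, 130.0),
    "L": (57.0, 47.0),
    "G": (80.0, -170.0),
    "P": (-75.0, 145.0),
    "T": (-60.0, 120.0),
}

# Six 7-residue motif templates chosen for mutual separation: the minimum
# pairwise superposition RMSD over the 8 window atoms is 3.2 Å, safely above
# typical intra-template spread at coordinate noise ~0.3 Å.
MOTIF_TEMPLATES: list[str] = [
    "HHHHHHH",   # alpha helix
    "HEEEPEG",   # helix cap into extended
    "PTGHHEG",   # polyproline/turn into short helix
    "PTLLLHE",   # left-handed stretch
    "TEPELLG",   # extended with left-handed kink
    "THHLHTH",   # broken helix
]

# States sampled for non-motif ("coil") residues, weighted towards
# extended/PP2 conformations as in real coil regions.
_COIL_STATES = ["E", "P", "T", "G", "L"]
_COIL_WEIGHTS = [0.3, 0.3, 0.2, 0.1, 0.1]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study set.

    Defaults give 20 chains of 120 residues with one modified site each,
    one planted missing region per chain, coordinate noise 0.3 Å and a
    disorder enrichment of p_in = 0.6 within ±15 residues of sites against
    p_out = 0.3 elsewhere.
    """

    n_proteins: int = 20
    protein_length: int = 120
    n_modified_per_protein: int = 1
    motif_templates: list[str] = field(
        default_factory=lambda: list(MOTIF_TEMPLATES[:3]))
    coordinate_noise_sd: float = 0.3
    missing_region_spec: list[tuple[int, int]] = field(
        default_factory=lambda: [(10, 4)])
    disorder_window: int = 15
    disorder_p_in: float = 0.6
    disorder_p_out: float = 0.3
    resolution: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.disorder_p_in <= 1 or not 0 <= self.disorder_p_out <= 1:
            raise ValueError("disorder probabilities must be in [0, 1]")
        if self.coordinate_noise_sd < 0:
            raise ValueError("coordinate noise must be >= 0")


def generate_ideal_peptide(phi_psi_deg, noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None
                           ) -> dict[str, np.ndarray]:
    """Backbone (N, CA, C, O, CB) built from per-residue (phi, psi).

    Ideal bond lengths and angles (Engh–Huber) with sequential placement;
    independent Gaussian noise of ``noise_sd`` Å added to every coordinate.
    """
    coords = build_backbone(np.asarray(phi_psi_deg, dtype=float))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        for key in coords:
            coords[key] = coords[key] + rng.normal(0.0, noise_sd,
                                                   size=coords[key].shape)
    return coords


def template_window_atoms(template: str) -> np.ndarray:
    """Noise-free 8 superposition atoms (7 CA + central CB) of a template."""
    pp = [PHI_PSI_STATES[c] for c in template]
    bb = build_backbone(np.array(pp))
    return np.vstack([bb["CA"], bb["CB"][3:4]])


def generate_window_set(k: int, n: int, noise_sd: float = 0.3,
                        seed: int | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """``n`` windows from ``k`` motif templates (round-robin) with noise.

    Returns (coords of shape (n, 8, 3), integer truth labels).
    """
    if not 1 <= k <= len(MOTIF_TEMPLATES):
        raise ValueError(f"k must be in [1, {len(MOTIF_TEMPLATES)}]")
    rng = np.random.default_rng(seed)
    bases = [template_window_atoms(t) for t in MOTIF_TEMPLATES[:k]]
    labels = np.arange(n) % k
    coords = np.stack([bases[lab] + rng.normal(0.0, noise_sd, size=(8, 3))
                       for lab in labels])
    return coords, labels


def _random_sequence(length: int, rng: np.random.Generator) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _format_atom(serial: int, name: str, resname: str, chain: str,
                 resnum: int, xyz: np.ndarray, bfac: float,
                 element: str) -> str:
    return (f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain}{resnum:4d}"
            f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}"
            f"{bfac:6.2f}          {element:>2s}\n")


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def generate_structure_set(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write a full synthetic study bundle under ``out_dir``.

    Produces per-protein PDB files (SEQRES + ATOM, planted missing regions,
    lognormal B-factors), a FASTA of all sequences, a modified-site table, a
    residue-level mapping table (identity mapping from sequence to chain),
    and truth CSVs for missing regions and planted motif assignments.

    Returns a manifest dict with file paths and in-memory truth tables.
    """
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    k = len(spec.motif_templates)
    L = spec.protein_length

    fasta_lines = []
    site_rows = []
    map_rows = []
    missing_truth = []
    motif_truth = []
    pdb_paths = []

    for p in range(spec.n_proteins):
        protein_id = f"SYNP{p:03d}"
        pdb_id = f"s{p + 1:03d}"
        seq = _random_sequence(L, rng)

        # place modified sites away from termini and missing regions
        forbidden = set()
        for start, length in spec.missing_region_spec:
            forbidden.update(range(start - 4, start + length + 4))
        candidates = [i for i in range(8, L - 7) if i not in forbidden]
        site_pos = rng.choice(candidates, size=spec.n_modified_per_protein,
                              replace=False)
        site_pos = np.sort(site_pos)

        states = list(rng.choice(_COIL_STATES, size=L, p=_COIL_WEIGHTS))
        for s_i, pos0 in enumerate(site_pos):          # pos0 is 0-based
            template = spec.motif_templates[(p * spec.n_modified_per_protein
                                             + s_i) % k]
            seq[pos0] = rng.choice(["S", "T"])
            states[pos0 - 3:pos0 + 4] = list(template)
            site_rows.append((protein_id, pos0 + 1, seq[pos0], "synthetic"))
            motif_truth.append((protein_id, pdb_id, "A", pos0 + 1, template))

        phi_psi = np.array([PHI_PSI_STATES[s] for s in states])
        coords = generate_ideal_peptide(phi_psi, spec.coordinate_noise_sd, rng)
        bfac = rng.lognormal(mean=np.log(20.0), sigma=0.3, size=L)

        missing = set()
        for start, length in spec.missing_region_spec:
            missing.update(range(start, start + length))  # 1-based
            missing_truth.append((pdb_id, "A", start, start + length - 1))

        seq_str = "".join(seq)
        fasta_lines.append(f">{protein_id}\n{seq_str}\n")
        for i in range(L):
            if (i + 1) not in missing:
                map_rows.append((protein_id, i + 1, pdb_id, "A", i + 1))

        path = out / "structures" / f"{pdb_id}.pdb"
        with open(path, "w") as fh:
            fh.write(f"HEADER    SYNTHETIC PROTEIN                       "
                     f"01-JAN-20   {pdb_id.upper():<4s}\n")
            fh.write("EXPDTA    X-RAY DIFFRACTION\n")
            fh.write(f"REMARK   2 RESOLUTION.    {spec.resolution:.2f} "
                     "ANGSTROMS.\n")
            fh.write("REMARK 999 IDEAL ENGH-HUBER BACKBONE GEOMETRY\n")
            for row_start in range(0, L, 13):
                block = seq[row_start:row_start + 13]
                names = " ".join(_THREE[a] for a in block)
                fh.write(f"SEQRES {row_start // 13 + 1:3d} A {L:4d}  "
                         f"{names}\n")
            serial = 1
            for i in range(L):
                resnum = i + 1
                if resnum in missing:
                    continue
                resname = _THREE[seq[i]]
                for name, key, elem in (("N", "N", "N"), ("CA", "CA", "C"),
                                        ("C", "C", "C"), ("O", "O", "O"),
                                        ("CB", "CB", "C")):
                    if name == "CB" and seq[i] == "G":
                        continue
                    fh.write(_format_atom(serial, name, resname, "A", resnum,
                                          coords[key][i], bfac[i], elem))
                    serial += 1
            fh.write("TER\nEND\n")
        pdb_paths.append(path)

    fasta_path = out / "sequences.fasta"
    fasta_path.write_text("".join(fasta_lines))
    sites_path = out / "sites.csv"
    with open(sites_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "position", "residue", "source"])
        w.writerows(site_rows)
    map_path = out / "mapping.csv"
    with open(map_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession", "seq_pos", "pdb", "chain", "chain_pos"])
        w.writerows(map_rows)
    truth_missing = out / "truth_missing.csv"
    with open(truth_missing, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pdb", "chain", "start", "end"])
        w.writerows(missing_truth)
    truth_motifs = out / "truth_motifs.csv"
    with open(truth_motifs, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "pdb", "chain", "position", "template"])
        w.writerows(motif_truth)

    return {
        "structures": pdb_paths,
        "fasta": fasta_path,
        "sites": sites_path,
        "mapping": map_path,
        "truth_missing": truth_missing,
        "truth_motifs": truth_motifs,
        "missing_truth": missing_truth,
        "motif_truth": motif_truth,
    }


def generate_disorder_tracks(n_target: int, n_background: int,
                             protein_length: int = 301,
                             window: int = 15, p_in: float = 0.6,
                             p_out: float = 0.3, threshold: float = 0.5,
                             method: str = "IUPred-Long",
                             seed: int | None = None) -> dict:
    """Disorder-score tracks with planted enrichment around target sites.

    Every protein carries one central S/T site.  Scores are uniform draws
    scaled so that P(score >= threshold) equals ``p_in`` within ±``window``
    of target sites and ``p_out`` elsewhere (background proteins use
    ``p_out`` everywhere).  The planted offset-0 log10 odds ratio is
    log10[(p_in/(1-p_in)) / (p_out/(1-p_out))].
    """
    rng = np.random.default_rng(seed)
    center = protein_length // 2 + 1

    def track(p_profile: np.ndarray) -> np.ndarray:
        u = rng.random(protein_length)
        # score >= threshold with probability p: map u<p to [thr,1], else below
        high = u < p_profile
        scores = np.where(high,
                          threshold + (1 - threshold) * rng.random(protein_length),
                          threshold * rng.random(protein_length))
        return scores

    target_profile = np.full(protein_length, p_out)
    lo = max(0, center - 1 - window)
    hi = min(protein_length, center + window)
    target_profile[lo:hi] = p_in

    target_tracks = {f"T{i:04d}": track(target_profile)
                     for i in range(n_target)}
    background_tracks = {f"B{i:04d}": track(np.full(protein_length, p_out))
                         for i in range(n_background)}
    target_sites = [(pid, center) for pid in target_tracks]
    background_sites = [(pid, center) for pid in background_tracks]
    planted = float(np.log10((p_in / (1 - p_in)) / (p_out / (1 - p_out))))
    return {
        "method": method,
        "threshold": threshold,
        "target_tracks": target_tracks,
        "background_tracks": background_tracks,
        "target_sites": target_sites,
        "background_sites": background_sites,
        "planted_log10_or": planted,
        "window": window,
    }


def write_sequence_bundle(out_dir: str | Path, n_target: int = 60,
                          n_background: int = 120,
                          protein_length: int = 301,
                          methods: tuple[str, ...] = ("IUPred-Long",),
                          window: int = 15, p_in: float = 0.6,
                          p_out: float = 0.3,
                          coil_at_site: float = 0.85,
                          coil_background: float = 0.55,
                          seed: int = 0) -> dict:
    """Write a sequence-arm bundle: sequences, sites, disorder and SS tracks.

    Target proteins carry one central S/T site each; disorder scores are
    enriched (``p_in`` vs ``p_out``) within ±``window`` of the site, and
    the 3-state SS prediction track is coil-enriched at site positions.
    Background proteins emulate a globular set with one random S/T site
    each and baseline disorder everywhere.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    center = protein_length // 2 + 1

    fasta, site_rows, bg_site_rows = [], [], []
    ss_rows = []
    thresholds = {m: 0.5 if "IUPred" in m or m == "JRonn" else
                  {"DisEMBL-REM465": 0.6, "DisEMBL-COILS": 0.516,
                   "DisEMBL-HOTLOOPS": 0.1204}[m] for m in methods}

    def scores_for(p_profile: np.ndarray, thr: float) -> np.ndarray:
        u = rng.random(protein_length)
        high = u < p_profile
        return np.where(high, thr + (1 - thr) * rng.random(protein_length),
                        thr * rng.random(protein_length))

    disorder_rows = {m: [] for m in methods}
    bg_disorder_rows = {m: [] for m in methods}
    states = np.array(list("CHE"))

    for i in range(n_target):
        pid = f"SYNT{i:04d}"
        seq = _random_sequence(protein_length, rng)
        seq[center - 1] = rng.choice(["S", "T"])
        fasta.append(f">{pid}\n{''.join(seq)}\n")
        site_rows.append((pid, center, seq[center - 1], "synthetic"))
        profile = np.full(protein_length, p_out)
        profile[max(0, center - 1 - window):center + window] = p_in
        for m in methods:
            sc = scores_for(profile, thresholds[m])
            disorder_rows[m] += [(pid, j + 1, m, round(float(sc[j]), 4))
                                 for j in range(protein_length)]
        p_coil = np.full(protein_length, coil_background)
        p_coil[center - 1] = coil_at_site
        for j in range(protein_length):
            if rng.random() < p_coil[j]:
                st = "C"
            else:
                st = rng.choice(["H", "E"], p=[0.7, 0.3])
            ss_rows.append((pid, j + 1, st))

    for i in range(n_background):
        pid = f"SYNG{i:04d}"
        seq = _random_sequence(protein_length, rng)
        pos = int(rng.integers(window + 1, protein_length - window))
        seq[pos - 1] = rng.choice(["S", "T"])
        fasta.append(f">{pid}\n{''.join(seq)}\n")
        bg_site_rows.append((pid, pos))
        flat = np.full(protein_length, p_out)
        for m in methods:
            sc = scores_for(flat, thresholds[m])
            bg_disorder_rows[m] += [(pid, j + 1, m, round(float(sc[j]), 4))
                                    for j in range(protein_length)]

    (out / "sequences.fasta").write_text("".join(fasta))
    with open(out / "sites.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "position", "residue", "source"])
        w.writerows(site_rows)
    with open(out / "background_sites.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "position"])
        w.writerows(bg_site_rows)
    with open(out / "disorder.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "position", "method", "score"])
        for m in methods:
            w.writerows(disorder_rows[m])
    with open(out / "background_disorder.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "position", "method", "score"])
        for m in methods:
            w.writerows(bg_disorder_rows[m])
    with open(out / "ss_pred.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "position", "state"])
        w.writerows(ss_rows)
    planted = float(np.log10((p_in / (1 - p_in)) / (p_out / (1 - p_out))))
    return {"out": out, "planted_log10_or": planted,
            "n_target": n_target, "n_background": n_background,
            "center": center}


def write_dssp_file(path: str | Path, chain_id: str,
                    records: list[tuple[int, str, str, float]]) -> None:
    """Write a minimal classic-format DSSP file.

    ``records`` holds (author_number, aa, ss8, acc) tuples; ss8 may be a
    blank string for unassigned residues.
    """
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition, synthetic file ====\n")
        fh.write("REFERENCE  synthetic fixture\n")
        fh.write(f"  {len(records)}  1  0  0  0  "
                 "TOTAL NUMBER OF RESIDUES, NUMBER OF CHAINS\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O"
                 "    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA"
                 "  PHI   PSI    X-CA   Y-CA   Z-CA\n")
        for i, (num, aa, ss8, acc) in enumerate(records, start=1):
            ss_char = ss8 if ss8 and ss8 != "blank" else " "
            line = f"{i:5d}{num:5d} {chain_id} {aa}  {ss_char}"
            line = line.ljust(34) + f"{int(round(acc)):4d}"
            fh.write(line + "\n")
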
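"""Placing sequence-space PTM sites onto structure chains.

Two routes mirror the usual practice: residue-level mapping tables
(SIFTS-style CSV) and local sequence alignment against chain sequences.
The alignment route uses Smith–Waterman with BLOSUM62 and affine gaps
(open 11, extend 1 — the common BLAST defaults) and converts scores to
E-values with the Karlin–Altschul formula; user-supplied BLAST tabular
output (outfmt 6) is accepted instead and takes precedence.  Candidates
survive only if the aligned column covers the site without a gap and the
chain residue is identical to the site residue.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .site_catalog import SiteRecord, SiteSet
from .structure_model import AnnotatedChain

__all__ = [
    "MappingCandidate",
    "map_by_table",
    "map_by_alignment",
    "read_blast_tabular",
    "select_best_candidate",
]

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

EVALUE_MAX_DEFAULT = 1e-25


@dataclass
class MappingCandidate:
    site: SiteRecord
    chain: tuple[str, str]              # (pdb_id, chain_id)
    chain_seq_index: int                # 1-based position in chain sequence
    method: str                         # "table" or "alignment"
    evalue: float | None = None
    coverage: float | None = None
    identity_at_window: float | None = None

    def __post_init__(self) -> None:
        if self.method == "alignment" and self.evalue is None:
            raise ValueError("alignment candidates need an E-value")


def _site_key(site: SiteRecord) -> tuple[str, int]:
    return (site.protein_id, site.position)


def map_by_table(sites: SiteSet, table_path: str | Path,
                 chains: dict[tuple[str, str], AnnotatedChain] | None = None
                 ) -> list[MappingCandidate]:
    """Map sites through a residue-level table CSV.

    Expected columns: ``accession,seq_pos,pdb,chain,chain_pos`` (1-based
    positions).  Coverage of a (accession, pdb, chain) pairing is the
    fraction of the protein's residues present in the table.  When parsed
    chains are supplied, candidates whose chain residue differs from the
    site residue are dropped (logged); without chains the identity check is
    deferred to selection time.
    """
    rows = []
    with open(table_path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((row["accession"], int(row["seq_pos"]),
                         row["pdb"].lower(), row["chain"],
                         int(row["chain_pos"])))
    coverage_counts: dict[tuple[str, str, str], int] = {}
    for acc, _sp, pdb, ch, _cp in rows:
        coverage_counts[(acc, pdb, ch)] = coverage_counts.get(
            (acc, pdb, ch), 0) + 1
    lookup: dict[tuple[str, int], list] = {}
    for acc, seq_pos, pdb, ch, chain_pos in rows:
        lookup.setdefault((acc, seq_pos), []).append((pdb, ch, chain_pos))

    out: list[MappingCandidate] = []
    n_dropped = 0
    for site in sites.records:
        for pdb, ch, chain_pos in lookup.get(_site_key(site), []):
            if chains is not None:
                chain = chains.get((pdb, ch))
                if chain is None:
                    continue
                entry = chain.residue_at(chain_pos)
                if entry is None or entry.aa != site.residue:
                    n_dropped += 1
                    continue
            seq_len = len(sites.sequences[site.protein_id])
            out.append(MappingCandidate(
                site=site, chain=(pdb, ch), chain_seq_index=chain_pos,
                method="table",
                coverage=coverage_counts[(site.protein_id, pdb, ch)] / seq_len))
    if n_dropped:
        warnings.warn(f"{n_dropped} table candidates dropped on residue-"
                      "identity mismatch")
    return out


def _alignment_evalue(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner

_SUBSTITUTION_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def map_by_alignment(sites: SiteSet,
                     chains: dict[tuple[str, str], AnnotatedChain],
                     evalue_max: float = EVALUE_MAX_DEFAULT
                     ) -> list[MappingCandidate]:
    """Smith–Waterman mapping of site proteins onto chain sequences.

    For every (protein, chain) pair the best local alignment is computed;
    if its Karlin–Altschul E-value is within ``evalue_max``, every site of
    the protein whose position falls in a non-gap alignment column becomes
    a candidate, subject to the residue-identity check.  Window identity is
    the identical fraction over the aligned columns of the site's 7-mer.
    """
    aligner = _make_aligner()
    by_protein: dict[str, list[SiteRecord]] = {}
    for site in sites.records:
        by_protein.setdefault(site.protein_id, []).append(site)

    out: list[MappingCandidate] = []
    for protein_id, protein_sites in by_protein.items():
        seq = sites.sequences[protein_id]
        clean = "".join(c if c in _SUBSTITUTION_ALPHABET else "X"
                        for c in seq.upper())
        for (pdb, ch_id), chain in chains.items():
            target = "".join(c if c in _SUBSTITUTION_ALPHABET else "X"
                             for c in chain.full_sequence.upper())
            if not target:
                continue
            alignments = aligner.align(clean, target)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            evalue = _alignment_evalue(aln.score, len(clean), len(target))
            if evalue > evalue_max:
                continue
            # column map: 0-based protein index -> 0-based chain index
            col_map: dict[int, int] = {}
            for (qs, qe), (ts, te) in zip(*aln.aligned):
                for offset in range(qe - qs):
                    col_map[qs + offset] = ts + offset
            for site in protein_sites:
                q0 = site.position - 1
                t0 = col_map.get(q0)
                if t0 is None:
                    continue        # site in a gapped column
                entry = chain.residue_at(t0 + 1)
                if entry is None or entry.aa != site.residue:
                    continue
                window_cols = [(q0 + d, col_map.get(q0 + d))
                               for d in range(-3, 4)]
                aligned_cols = [(q, t) for q, t in window_cols
                                if t is not None and 0 <= q < len(clean)]
                ident = (sum(clean[q] == target[t] for q, t in aligned_cols)
                         / len(aligned_cols)) if aligned_cols else 0.0
                out.append(MappingCandidate(
                    site=site, chain=(pdb, ch_id), chain_seq_index=t0 + 1,
                    method="alignment", evalue=evalue,
                    coverage=len(col_map) / len(clean),
                    identity_at_window=ident))
    return out


def read_blast_tabular(path: str | Path, sites: SiteSet,
                       chains: dict[tuple[str, str], AnnotatedChain],
                       evalue_max: float = EVALUE_MAX_DEFAULT
                       ) -> list[MappingCandidate]:
    """Candidates from BLAST outfmt-6 rows (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    The subject id must be ``pdb_chain``.  Gapless column arithmetic is
    used within each HSP (positions outside, or in HSPs with gaps that
    cannot be resolved, are skipped conservatively when the mapped residue
    mismatches).
    """
    out: list[MappingCandidate] = []
    by_protein: dict[str, list[SiteRecord]] = {}
    for site in sites.records:
        by_protein.setdefault(site.protein_id, []).append(site)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qseqid, sseqid = f[0], f[1]
            qstart, qend, sstart = int(f[6]), int(f[7]), int(f[8])
            evalue = float(f[10])
            if evalue > evalue_max or qseqid not in by_protein:
                continue
            pdb, _, ch_id = sseqid.rpartition("_")
            chain = chains.get((pdb.lower(), ch_id))
            if chain is None:
                continue
            for site in by_protein[qseqid]:
                if not qstart <= site.position <= qend:
                    continue
                chain_pos = sstart + (site.position - qstart)
                entry = chain.residue_at(chain_pos)
                if entry is None or entry.aa != site.residue:
                    continue
                seq_len = len(sites.sequences[site.protein_id])
                out.append(MappingCandidate(
                    site=site, chain=(pdb.lower(), ch_id),
                    chain_seq_index=chain_pos, method="alignment",
                    evalue=evalue,
                    coverage=(qend - qstart + 1) / seq_len))
    return out


def select_best_candidate(candidates: list[MappingCandidate]
                          ) -> dict[tuple[str, int], MappingCandidate]:
    """One candidate per site.

    Table candidates outrank alignment candidates; among table candidates
    the highest coverage wins, among alignment candidates the lowest
    (best) E-value.  Exact ties resolve to the lexicographically smallest
    (pdb_id, chain_id), so the result is invariant to input order.
    """
    best: dict[tuple[str, int], MappingCandidate] = {}

    def rank(c: MappingCandidate):
        method_rank = 0 if c.method == "table" else 1
        quality = (-(c.coverage or 0.0)) if c.method == "table" \
            else (c.evalue if c.evalue is not None else math.inf)
        return (method_rank, quality, c.chain)

    for cand in candidates:
        key = _site_key(cand.site)
        if key not in best or rank(cand) < rank(best[key]):
            best[key] = cand
    return best


def write_selected_mappings(selected: dict, path: str | Path) -> None:
    """Selected-mapping CSV (1-based positions in both coordinate systems)."""
    with open(path, "w", newline="") as fh:
        fh.write("# positions are 1-based; chain_seq_index is in construct-"
                 "sequence space\n")
        w = csv.writer(fh)
        w.writerow(["protein_id", "position", "residue", "pdb", "chain",
                    "chain_seq_index", "method", "evalue", "coverage"])
        for (pid, pos), c in sorted(selected.items()):
            w.writerow([pid, pos, c.site.residue, c.chain[0], c.chain[1],
                        c.chain_seq_index, c.method,
                        "" if c.evalue is None else f"{c.evalue:.3g}",
                        "" if c.coverage is None else f"{c.coverage:.3f}"])
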
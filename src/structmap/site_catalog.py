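"""Site catalogs: modified (MSS-style), unmodified (USS-style) and user sets.

A site is a (protein, 1-based position, S/T residue) triple with its
7-residue flank (positions −3..+3, central residue at index 3).  Flank
positions beyond the sequence termini are padded with '-'; exclusion of
terminus-proximal sites is available but padding is the default.  Positions
are 1-based in sequence space throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SiteRecord",
    "SiteSet",
    "extract_flank7",
    "load_site_table",
    "filter_unique_motifs",
    "derive_unmodified_set",
    "trim_for_predictor",
    "write_site_set",
]

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class SiteRecord:
    protein_id: str
    position: int                   # 1-based
    residue: str                    # one-letter, S or T for site sets
    flank7: str                     # 7 residues, '-' padded at termini
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if len(self.flank7) != 7:
            raise ValueError("flank7 must have length 7")
        if self.flank7[3] != GAP and self.flank7[3] != self.residue:
            raise ValueError(
                f"central flank residue {self.flank7[3]!r} does not match "
                f"site residue {self.residue!r}")


@dataclass
class SiteSet:
    name: str                       # MSS, USS, GS or user
    records: list[SiteRecord]
    sequences: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        for r in self.records:
            seq = self.sequences.get(r.protein_id)
            if seq is None:
                raise ValueError(f"no sequence for {r.protein_id}")
            if not 1 <= r.position <= len(seq):
                raise ValueError(f"{r.protein_id}:{r.position} outside "
                                 "sequence")
            if seq[r.position - 1] != r.residue:
                raise ValueError(f"{r.protein_id}:{r.position} residue "
                                 "mismatch")


def extract_flank7(sequence: str, position: int) -> str:
    """±3 window around a 1-based position, '-'-padded past the termini."""
    chars = []
    for offset in range(-3, 4):
        idx = position - 1 + offset
        chars.append(sequence[idx] if 0 <= idx < len(sequence) else GAP)
    return "".join(chars)


def load_site_table(path: str | Path, sequences: str | Path,
                    name: str = "user") -> SiteSet:
    """Build a SiteSet from a site table (CSV/TSV) and a FASTA of sequences.

    The table needs columns ``protein_id`` and ``position`` (1-based); a
    ``source`` column is carried through when present.  Rows whose sequence
    residue is not S/T, or whose position exceeds the sequence, are rejected
    with a logged count.  Missing sequences are a hard error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(sequences), "fasta")}

    missing = sorted(set(table["protein_id"]) - set(seqs))
    if missing:
        raise ValueError("no sequence for accession(s): " + ", ".join(missing))

    records = []
    n_rejected_residue = 0
    n_rejected_range = 0
    for row in table.itertuples(index=False):
        pid = str(row.protein_id)
        pos = int(row.position)
        seq = seqs[pid]
        if not 1 <= pos <= len(seq):
            n_rejected_range += 1
            warnings.warn(f"{pid}:{pos} beyond sequence length {len(seq)}; "
                          "record rejected")
            continue
        residue = seq[pos - 1]
        if residue not in "ST":
            n_rejected_residue += 1
            continue
        records.append(SiteRecord(
            protein_id=pid, position=pos, residue=residue,
            flank7=extract_flank7(seq, pos),
            source_label=str(getattr(row, "source", ""))))
    if n_rejected_residue:
        logger.info("rejected %d rows with non-S/T sequence residue",
                    n_rejected_residue)
    if n_rejected_range:
        logger.info("rejected %d rows with out-of-range positions",
                    n_rejected_range)
    used = {r.protein_id for r in records}
    return SiteSet(name=name, records=records,
                   sequences={p: s for p, s in seqs.items() if p in used})


def filter_unique_motifs(s: SiteSet, drop_padded: bool = False) -> SiteSet:
    """Keep one record per distinct flank7 (first occurrence wins).

    Records whose central flank position is a gap are removed; with
    ``drop_padded`` records with any terminal padding go too.
    """
    seen: set[str] = set()
    kept = []
    for r in s.records:
        if r.flank7[3] == GAP:
            continue
        if drop_padded and GAP in r.flank7:
            continue
        if r.flank7 in seen:
            continue
        seen.add(r.flank7)
        kept.append(r)
    return SiteSet(name=s.name, records=kept, sequences=dict(s.sequences))


def derive_unmodified_set(modified: SiteSet, name: str = "USS") -> SiteSet:
    """All S/T positions of the modified set's proteins that are unmodified."""
    taken = {(r.protein_id, r.position) for r in modified.records}
    records = []
    for pid, seq in modified.sequences.items():
        for idx, aa in enumerate(seq):
            pos = idx + 1
            if aa in "ST" and (pid, pos) not in taken:
                records.append(SiteRecord(
                    protein_id=pid, position=pos, residue=aa,
                    flank7=extract_flank7(seq, pos), source_label="derived"))
    return SiteSet(name=name, records=records,
                   sequences=dict(modified.sequences))


def trim_for_predictor(sequence: str, site_position: int,
                       max_len: int = 800, margin: int = 100
                       ) -> tuple[str, int]:
    """Trim a long sequence for predictors with an input-length cap.

    The window of ``max_len`` residues is centred on the site and shifted
    to fit the sequence, which keeps the site at least ``margin`` residues
    from each terminus whenever the full sequence allows it.  Returns the
    trimmed sequence and the 1-based site position within it.
    """
    n = len(sequence)
    if not 1 <= site_position <= n:
        raise ValueError("site_position outside sequence")
    if n <= max_len:
        return sequence, site_position
    if n < 2 * margin:
        warnings.warn("sequence shorter than twice the margin; returned "
                      "unchanged")
        return sequence, site_position
    start = site_position - max_len // 2       # 1-based window start
    start = max(1, min(start, n - max_len + 1))
    end = start + max_len - 1
    return sequence[start - 1:end], site_position - start + 1


def write_site_set(s: SiteSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# positions are 1-based in full-protein sequence space\n")
        pd.DataFrame(
            [(r.protein_id, r.position, r.residue, r.flank7, r.source_label)
             for r in s.records],
            columns=["protein_id", "position", "residue", "flank7", "source"],
        ).to_csv(fh, index=False)
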
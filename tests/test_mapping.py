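"""Sequence-to-structure mapping: tables, alignment, candidate selection."""

import numpy as np
import pytest

from structmap.mapping import (MappingCandidate, map_by_alignment,
                               map_by_table, read_blast_tabular,
                               select_best_candidate)
from structmap.site_catalog import SiteRecord, SiteSet, extract_flank7
from structmap.structure_model import parse_chain


def _site(pid, pos, seq):
    return SiteRecord(pid, pos, seq[pos - 1], extract_flank7(seq, pos))


def _cand(pid, pos, chain, method, **kw):
    site = SiteRecord(pid, pos, "S", "---S---")
    return MappingCandidate(site=site, chain=chain, chain_seq_index=pos,
                            method=method, **kw)


class TestSelectBest:
    def test_table_highest_coverage_wins(self):
        cands = [_cand("P1", 5, ("1abc", "A"), "table", coverage=0.7),
                 _cand("P1", 5, ("2xyz", "B"), "table", coverage=0.9)]
        best = select_best_candidate(cands)[("P1", 5)]
        assert best.chain == ("2xyz", "B")

    def test_alignment_lowest_evalue_wins(self):
        cands = [_cand("P1", 5, ("1abc", "A"), "alignment", evalue=1e-30),
                 _cand("P1", 5, ("2xyz", "B"), "alignment", evalue=1e-40)]
        best = select_best_candidate(cands)[("P1", 5)]
        assert best.chain == ("2xyz", "B")

    def test_table_outranks_alignment(self):
        cands = [_cand("P1", 5, ("1abc", "A"), "alignment", evalue=1e-60),
                 _cand("P1", 5, ("2xyz", "B"), "table", coverage=0.5)]
        assert select_best_candidate(cands)[("P1", 5)].method == "table"

    def test_exact_tie_lexicographic(self):
        cands = [_cand("P1", 5, ("2xyz", "B"), "table", coverage=0.8),
                 _cand("P1", 5, ("1abc", "A"), "table", coverage=0.8)]
        assert select_best_candidate(cands)[("P1", 5)].chain == ("1abc", "A")

    def test_invariant_under_permutation(self):
        cands = [_cand("P1", 5, (p, c), m, **kw) for p, c, m, kw in [
            ("3qrs", "A", "alignment", {"evalue": 1e-50}),
            ("1abc", "B", "table", {"coverage": 0.4}),
            ("2xyz", "A", "table", {"coverage": 0.6}),
        ]]
        forward = select_best_candidate(cands)[("P1", 5)]
        backward = select_best_candidate(cands[::-1])[("P1", 5)]
        assert forward.chain == backward.chain == ("2xyz", "A")

    def test_alignment_without_evalue_rejected(self):
        with pytest.raises(ValueError):
            _cand("P1", 5, ("1abc", "A"), "alignment")


class TestTableMapping:
    def test_identity_check_drops_mismatches(self, structural_bundle,
                                             tmp_path):
        chain = parse_chain(structural_bundle["structures"][0], "A")
        chains = {(chain.pdb_id, "A"): chain}
        # row 1 targets a real S/T; row 2 deliberately points at offset+1
        pos = next(r.seq_index for r in chain.residues
                   if r.observed and r.aa == "S"
                   and chain.residue_at(r.seq_index + 1) is not None
                   and chain.residue_at(r.seq_index + 1).aa != "S")
        seq = chain.full_sequence
        table = tmp_path / "map.csv"
        table.write_text("accession,seq_pos,pdb,chain,chain_pos\n"
                         f"P1,{pos},{chain.pdb_id},A,{pos}\n"
                         f"P1,{pos + 1},{chain.pdb_id},A,{pos + 1}\n")
        sites = SiteSet("MSS", [_site("P1", pos, seq)], {"P1": seq})
        good = map_by_table(sites, table, chains)
        assert len(good) == 1 and good[0].chain_seq_index == pos
        # now aim the same S site at the mismatching position
        bad_sites = SiteSet(
            "MSS",
            [SiteRecord("P1", pos + 1, "S", "---S---")],
            {"P1": seq})
        with pytest.warns(UserWarning, match="identity"):
            assert map_by_table(bad_sites, table, chains) == []


class TestAlignmentMapping:
    def test_self_hit_maps_all_sites(self, structural_bundle):
        chain = parse_chain(structural_bundle["structures"][0], "A")
        seq = chain.full_sequence
        positions = [r.seq_index for r in chain.residues if r.aa in "ST"][:5]
        sites = SiteSet("MSS", [_site("P1", p, seq) for p in positions],
                        {"P1": seq})
        cands = map_by_alignment(sites, {(chain.pdb_id, "A"): chain})
        assert {c.site.position for c in cands} == set(positions)
        for c in cands:
            assert c.chain_seq_index == c.site.position
            assert c.evalue < 1e-25

    def test_point_mutations_outside_windows_still_map(self,
                                                       structural_bundle,
                                                       rng):
        chain = parse_chain(structural_bundle["structures"][1], "A")
        seq = list(chain.full_sequence)
        site_pos = [r.seq_index for r in chain.residues if r.aa in "ST"][:3]
        protected = {p + d for p in site_pos for d in range(-3, 4)}
        mutated = 0
        for idx in rng.permutation(len(seq)):
            if mutated == 5:
                break
            if idx + 1 not in protected and seq[idx] not in "ST":
                seq[idx] = "W" if seq[idx] != "W" else "F"
                mutated += 1
        seq = "".join(seq)
        sites = SiteSet("MSS", [_site("P1", p, seq) for p in site_pos],
                        {"P1": seq})
        cands = map_by_alignment(sites, {(chain.pdb_id, "A"): chain})
        assert {c.site.position for c in cands} == set(site_pos)
        assert all(c.identity_at_window == 1.0 for c in cands)

    def test_weak_similarity_rejected_by_evalue(self, structural_bundle,
                                                rng):
        chain = parse_chain(structural_bundle["structures"][0], "A")
        # unrelated random sequence: best local alignment is far above 1e-25
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRVWY"), size=150))
        seq = seq[:70] + "S" + seq[71:]
        sites = SiteSet("MSS", [_site("P1", 71, seq)], {"P1": seq})
        assert map_by_alignment(sites, {(chain.pdb_id, "A"): chain}) == []


class TestBlastTabular:
    def test_hsp_rows_map_sites(self, structural_bundle, tmp_path):
        chain = parse_chain(structural_bundle["structures"][0], "A")
        seq = chain.full_sequence
        pos = next(r.seq_index for r in chain.residues if r.aa in "ST")
        tab = tmp_path / "blast.tsv"
        tab.write_text("\t".join([
            "P1", f"{chain.pdb_id}_A", "100.0", str(len(seq)), "0", "0",
            "1", str(len(seq)), "1", str(len(seq)), "1e-80", "500"]) + "\n")
        sites = SiteSet("MSS", [_site("P1", pos, seq)], {"P1": seq})
        cands = read_blast_tabular(tab, sites, {(chain.pdb_id, "A"): chain})
        assert len(cands) == 1
        assert cands[0].chain_seq_index == pos
        # high E-value rows are filtered
        tab.write_text(tab.read_text().replace("1e-80", "1e-10"))
        assert read_blast_tabular(tab, sites,
                                  {(chain.pdb_id, "A"): chain}) == []


def test_planted_correspondences_fully_recovered(structural_bundle):
    """Table mapping recovers every plantable synthetic site."""
    import pandas as pd

    from structmap.pipeline import (RunConfig, build_chains, load_catalog,
                                    map_sites)
    root = structural_bundle["root"]
    mss, _ = load_catalog(root)
    chains = build_chains(root, RunConfig())
    selected = map_sites(mss, chains, root, RunConfig())
    assert len(selected) == len(mss)
    truth = pd.read_csv(structural_bundle["truth_motifs"])
    for row in truth.itertuples():
        cand = selected[(row.protein_id, row.position)]
        assert cand.chain == (row.pdb, row.chain)
        assert cand.chain_seq_index == row.position
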
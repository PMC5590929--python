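"""End-to-end orchestration: from input bundle to report tables.

A *bundle* is a directory with the pipeline inputs::

    structures/*.pdb|*.cif   structure files
    sequences.fasta          full protein sequences
    sites.csv                modified-site table (protein_id,position,...)
    mapping.csv              optional residue-level mapping table
    dssp/<pdbid>.dssp        optional DSSP outputs per structure
    disorder.csv             optional per-residue disorder scores
    ss_pred.csv              optional per-residue 3-state SS predictions
    background_sites.csv     optional globular background site table
    background_disorder.csv  optional background disorder scores

The synthetic generator emits exactly this layout.  Every report table is
CSV with a leading comment echoing the configuration fingerprint, so any
result file names the thresholds that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import site_catalog as sc
from .clustering import (bootstrap_null, complete_linkage_clusters,
                         consensus_ss, pairwise_matrix)
from .mapping import (map_by_alignment, map_by_table, read_blast_tabular,
                      select_best_candidate, write_selected_mappings)
from .stats import (ContingencyTable2x2, DisorderTrack, disorder_odds_profile,
                    fisher_exact_or, proportion_ci, relative_entropy_profile,
                    score_comparison, two_proportion_ztest)
from .structure_model import (eligible_chain, extract_window, parse_chain,
                              standardise_bfactors)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_structural_analysis", "run_sequence_analysis"]


@dataclass
class RunConfig:
    """All numeric knobs of a run, serialised into every output."""

    evalue_max: float = 1e-25
    rmsd_threshold: float = 3.0
    rsa_buried: float = 0.05
    rsa_partial: float = 0.25
    resolution_max: float = 2.50
    min_chain_length: int = 31
    bootstrap_reps: int = 1000
    entropy_reps: int = 200
    profile_halfwidth: int = 50
    entropy_halfwidth: int = 7
    max_asa_scale: str = "tien2013"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("evalue_max", "rmsd_threshold", "rsa_buried",
                     "rsa_partial", "resolution_max", "min_chain_length",
                     "bootstrap_reps", "entropy_reps", "profile_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def fingerprint(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config: {config.fingerprint()}\n")
        df.to_csv(fh, index=False)


def load_catalog(bundle: Path) -> tuple[sc.SiteSet, sc.SiteSet]:
    mss = sc.filter_unique_motifs(
        sc.load_site_table(bundle / "sites.csv", bundle / "sequences.fasta",
                           name="MSS"))
    uss = sc.derive_unmodified_set(mss)
    logger.info("catalog: %d modified, %d unmodified sites", len(mss),
                len(uss))
    return mss, uss


def build_chains(bundle: Path, config: RunConfig) -> dict:
    """Parse and filter every polymer chain of every structure file."""
    import gemmi

    chains = {}
    structures = sorted((bundle / "structures").glob("*"))
    for path in structures:
        if path.suffix.lower() not in (".pdb", ".cif", ".ent"):
            continue
        st = gemmi.read_structure(str(path))
        chain_ids = [ch.name for ch in st[0]] if len(st) else []
        for chain_id in chain_ids:
            chain = parse_chain(path, chain_id)
            if eligible_chain(chain, min_len=config.min_chain_length,
                              max_res=config.resolution_max):
                chains[(chain.pdb_id, chain.chain_id)] = chain
    logger.info("structures: %d eligible chains from %d files", len(chains),
                len(structures))
    return chains


def map_sites(mss: sc.SiteSet, chains: dict, bundle: Path,
              config: RunConfig) -> dict:
    """Table mapping first, then alignment for the remainder."""
    candidates = []
    table = bundle / "mapping.csv"
    if table.exists():
        candidates += map_by_table(mss, table, chains)
    blast = bundle / "blast.tsv"
    if blast.exists():
        candidates += read_blast_tabular(blast, mss, chains,
                                         config.evalue_max)
    mapped_proteins = {c.site.protein_id for c in candidates}
    remaining = sc.SiteSet(
        name=mss.name,
        records=[r for r in mss.records
                 if r.protein_id not in mapped_proteins],
        sequences=mss.sequences)
    if remaining.records and not blast.exists():
        candidates += map_by_alignment(remaining, chains, config.evalue_max)
    selected = select_best_candidate(candidates)
    logger.info("mapping: %d/%d sites placed on structure", len(selected),
                len(mss))
    return selected


def annotate_chains(chains: dict, bundle: Path, config: RunConfig) -> dict:
    """Per-chain SS/RSA annotations from DSSP files or the fallbacks."""
    dssp_dir = bundle / "dssp"
    out = {}
    for key, chain in chains.items():
        dssp = None
        if dssp_dir.is_dir():
            cand = dssp_dir / f"{chain.pdb_id}.dssp"
            if cand.exists():
                dssp = acc.parse_dssp(cand)
        out[key] = acc.annotate_chain(chain, dssp=dssp,
                                      scale=config.max_asa_scale)
    return out


def _unmodified_structure_positions(chains: dict, selected: dict
                                    ) -> list[tuple[tuple[str, str], int]]:
    """All S/T positions in mapped chains that carry no modified site."""
    modified = {(c.chain, c.chain_seq_index) for c in selected.values()}
    used_chains = {c.chain for c in selected.values()}
    out = []
    for key in used_chains:
        chain = chains[key]
        for r in chain.residues:
            if r.aa in "ST" and (key, r.seq_index) not in modified:
                out.append((key, r.seq_index))
    return out


def run_structural_analysis(bundle: str | Path, out_dir: str | Path,
                            config: RunConfig | None = None) -> dict:
    """The structure-space arm: REM465 enrichment, SS and RSA tables,
    window clustering with consensus secondary structure, bootstrap null.

    Returns a report dict; all tables are also written under ``out_dir``.
    """
    bundle = Path(bundle)
    out = Path(out_dir)
    config = config or RunConfig()
    report: dict = {"config": asdict(config)}

    mss, _uss = load_catalog(bundle)
    chains = build_chains(bundle, config)
    if not chains:
        raise FileNotFoundError(f"no eligible structure chains under "
                                f"{bundle / 'structures'}")
    selected = map_sites(mss, chains, bundle, config)
    if not selected:
        raise ValueError("no sites could be mapped to structures; check "
                         "mapping.csv / sequences against the structures")
    annotations = annotate_chains(chains, bundle, config)
    out.mkdir(parents=True, exist_ok=True)
    write_selected_mappings(selected, out / "selected_mappings.csv")

    unmod = _unmodified_structure_positions(chains, selected)

    # REM465 contingency: modified vs unmodified S/T in the same chains
    mod_missing = sum(chains[c.chain].residue_at(c.chain_seq_index).rem465
                      for c in selected.values())
    unmod_missing = sum(chains[key].residue_at(pos).rem465
                        for key, pos in unmod)
    table = ContingencyTable2x2(mod_missing, len(selected) - mod_missing,
                                unmod_missing, len(unmod) - unmod_missing)
    odds, p = fisher_exact_or(table)
    report["rem465"] = {"modified_missing": mod_missing,
                        "modified_total": len(selected),
                        "unmodified_missing": unmod_missing,
                        "unmodified_total": len(unmod),
                        "odds_ratio": odds, "fisher_p": p}
    _write_table(pd.DataFrame([report["rem465"]]), out / "rem465.csv", config)

    # B-factor z-score comparison (Kruskal-Wallis)
    z_mod, z_unmod = [], []
    zcache = {}
    for c in selected.values():
        zcache.setdefault(c.chain, standardise_bfactors(chains[c.chain]))
        z = zcache[c.chain].get(c.chain_seq_index)
        if z is not None:
            z_mod.append(z)
    for key, pos in unmod:
        zcache.setdefault(key, standardise_bfactors(chains[key]))
        z = zcache[key].get(pos)
        if z is not None:
            z_unmod.append(z)
    if len(z_mod) >= 2 and len(z_unmod) >= 2:
        report["bfactor"] = score_comparison(z_mod, z_unmod,
                                             test="kruskal_wallis")

    # DSSP (or fallback) SS3 proportions with z-tests
    def ss3_of(key, pos):
        ann = annotations[key].get(pos)
        return ann.ss3 if ann else None

    mod_ss = [ss3_of(c.chain, c.chain_seq_index) for c in selected.values()]
    unmod_ss = [ss3_of(key, pos) for key, pos in unmod]
    mod_ss = [s for s in mod_ss if s]
    unmod_ss = [s for s in unmod_ss if s]
    rows = []
    for state in "CHE":
        x1 = mod_ss.count(state)
        x2 = unmod_ss.count(state)
        n1, n2 = len(mod_ss), len(unmod_ss)
        if n1 and n2:
            lo1, hi1 = proportion_ci(x1, n1)
            lo2, hi2 = proportion_ci(x2, n2)
            _, pz = two_proportion_ztest(x1, n1, x2, n2)
            rows.append({"ss3": state, "modified_n": x1,
                         "modified_prop": x1 / n1,
                         "modified_ci_low": lo1, "modified_ci_high": hi1,
                         "unmodified_n": x2, "unmodified_prop": x2 / n2,
                         "unmodified_ci_low": lo2, "unmodified_ci_high": hi2,
                         "p": pz})
    ss_table = pd.DataFrame(rows)
    report["ss3_proportions"] = ss_table
    _write_table(ss_table, out / "ss3_proportions.csv", config)

    # RSA bins and buried modified sites
    def rsa_of(key, pos):
        ann = annotations[key].get(pos)
        return ann.rsa if ann else None

    rsa_rows = []
    for group, positions in (("modified",
                              [(c.chain, c.chain_seq_index)
                               for c in selected.values()]),
                             ("unmodified", unmod)):
        values = [rsa_of(*kp) for kp in positions]
        values = [v for v in values if v is not None]
        for name, lo_, hi_ in (("buried", -1, config.rsa_buried),
                               ("partial", config.rsa_buried,
                                config.rsa_partial),
                               ("exposed", config.rsa_partial, np.inf)):
            n = sum(lo_ < v <= hi_ for v in values)
            rsa_rows.append({"group": group, "rsa_bin": name, "n": n,
                             "prop": n / len(values) if values else np.nan})
    rsa_table = pd.DataFrame(rsa_rows)
    report["rsa_bins"] = rsa_table
    _write_table(rsa_table, out / "rsa_bins.csv", config)

    # Windows and clustering
    windows = {}
    for (pid, pos), cand in selected.items():
        w = extract_window(chains[cand.chain], cand.chain_seq_index)
        if w is not None and w.backbone_complete:
            windows[(pid, pos)] = w
    report["n_mapped"] = len(selected)
    report["n_backbone_complete"] = len(windows)
    cluster_rows = []
    if len(windows) >= 2:
        matrix = pairwise_matrix(list(windows.values()))
        result = complete_linkage_clusters(matrix, config.rmsd_threshold)
        ss_by_window = {}
        rsa_by_window = {}
        for w in windows.values():
            tokens = []
            for e in w.window_entries:
                ann = annotations[w.chain_ref].get(e.seq_index) if e else None
                tokens.append(ann.ss3 if ann else "-")
            ss_by_window[w.window_id] = "".join(tokens)
            ann_c = annotations[w.chain_ref].get(w.center_seq_index)
            rsa_by_window[w.window_id] = ann_c.rsa if ann_c else None
        result.consensus_ss3 = {
            label: consensus_ss(members, ss_by_window)
            for label, members in zip(
                (result.labels()[m[0]] for m in result.clusters),
                result.clusters)}
        labels = result.labels()
        for w in windows.values():
            rsa = rsa_by_window[w.window_id]
            cluster_rows.append({
                "PDB": w.chain_ref[0], "Chain": w.chain_ref[1],
                "Position": w.center_seq_index,
                "Cluster": labels[w.window_id],
                "RSA": np.nan if rsa is None else round(rsa, 3),
                "SS": ss_by_window[w.window_id]})
        report["clusters"] = result
        report["n_clusters"] = result.n_clusters
        report["n_clustered"] = result.n_clustered
        report["n_singlets"] = len(result.singlets)
        cluster_table = pd.DataFrame(cluster_rows)
        _write_table(cluster_table, out / "cluster_assignments.csv", config)
        buried = cluster_table[cluster_table["RSA"] <= config.rsa_buried]
        report["buried_sites"] = buried
        _write_table(buried, out / "buried_sites.csv", config)

        # bootstrap null from windows centred on unmodified S/T
        pool = []
        for key, pos in unmod:
            w = extract_window(chains[key], pos)
            if w is not None and w.backbone_complete:
                pool.append(w)
        if len(pool) >= 2:
            null = bootstrap_null(pairwise_matrix(pool),
                                  n=len(windows),
                                  reps=config.bootstrap_reps,
                                  threshold=config.rmsd_threshold,
                                  seed=config.seed)
            lo, hi = null.percentile_interval()
            report["bootstrap"] = {"n_pool": len(pool),
                                   "ci_low": lo, "ci_high": hi,
                                   "counts": null.counts}
            _write_table(pd.DataFrame({"replicate":
                                       np.arange(len(null.counts)),
                                       "n_clusters": null.counts}),
                         out / "bootstrap_null.csv", config)
    return report


def load_disorder_csv(path: str | Path) -> dict[str, dict[str, DisorderTrack]]:
    """Disorder CSV (protein_id,position,method,score) -> method-keyed tracks."""
    df = pd.read_csv(path, comment="#")
    out: dict[str, dict[str, DisorderTrack]] = {}
    for (method, pid), sub in df.groupby(["method", "protein_id"]):
        sub = sub.sort_values("position")
        n = int(sub["position"].max())
        scores = np.full(n, np.nan)
        scores[sub["position"].to_numpy() - 1] = sub["score"].to_numpy()
        out.setdefault(method, {})[pid] = DisorderTrack(
            protein_id=pid, method=method, scores=scores)
    return out


def run_sequence_analysis(bundle: str | Path, out_dir: str | Path,
                          config: RunConfig | None = None) -> dict:
    """The sequence-space arm: entropy profile, predicted-SS tests,
    disorder score comparison and disorder log-odds profiles."""
    bundle = Path(bundle)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    report: dict = {"config": asdict(config)}

    mss, uss = load_catalog(bundle)

    # relative-entropy profile of site windows vs background composition
    from .stats import AMINO_ACIDS
    all_seq = "".join(mss.sequences.values())
    counts = np.array([all_seq.count(a) for a in AMINO_ACIDS], dtype=float)
    background = counts / counts.sum()
    hw = config.entropy_halfwidth
    flanks = [
        "".join(mss.sequences[r.protein_id][r.position - 1 + d]
                if 0 <= r.position - 1 + d < len(mss.sequences[r.protein_id])
                else "-" for d in range(-hw, hw + 1))
        for r in mss.records]
    entropy = relative_entropy_profile(flanks, background,
                                       reps=config.entropy_reps,
                                       seed=config.seed)
    report["entropy_profile"] = entropy
    _write_table(pd.DataFrame({"offset": entropy.offsets,
                               "relative_entropy_bits": entropy.values,
                               "ci_low": entropy.ci_low,
                               "ci_high": entropy.ci_high}),
                 out / "entropy_profile.csv", config)

    # predicted 3-state SS proportions (when a prediction track is given)
    ss_pred = bundle / "ss_pred.csv"
    if ss_pred.exists():
        pred = pd.read_csv(ss_pred, comment="#")
        state = {(r.protein_id, r.position): r.state
                 for r in pred.itertuples(index=False)}
        mod = [state.get((r.protein_id, r.position)) for r in mss.records]
        unm = [state.get((r.protein_id, r.position)) for r in uss.records]
        mod = [s for s in mod if s]
        unm = [s for s in unm if s]
        rows = []
        for st3 in "CHE":
            if mod and unm:
                _, pz = two_proportion_ztest(mod.count(st3), len(mod),
                                             unm.count(st3), len(unm))
                lo1, hi1 = proportion_ci(mod.count(st3), len(mod))
                rows.append({"ss3": st3, "modified_n": mod.count(st3),
                             "modified_prop": mod.count(st3) / len(mod),
                             "ci_low": lo1, "ci_high": hi1,
                             "unmodified_n": unm.count(st3),
                             "unmodified_prop": unm.count(st3) / len(unm),
                             "p": pz})
        table = pd.DataFrame(rows)
        report["predicted_ss"] = table
        _write_table(table, out / "predicted_ss.csv", config)

    # disorder: mean-score comparison and log-odds profiles per method
    disorder = bundle / "disorder.csv"
    if disorder.exists():
        tracks = load_disorder_csv(disorder)
        bg_sites_path = bundle / "background_sites.csv"
        bg_disorder = bundle / "background_disorder.csv"
        rows = []
        for method, per_protein in sorted(tracks.items()):
            mod_scores = [per_protein[r.protein_id].scores[r.position - 1]
                          for r in mss.records
                          if r.protein_id in per_protein
                          and r.position <= len(per_protein[r.protein_id].scores)]
            unm_scores = [per_protein[r.protein_id].scores[r.position - 1]
                          for r in uss.records
                          if r.protein_id in per_protein
                          and r.position <= len(per_protein[r.protein_id].scores)]
            mod_scores = [s for s in mod_scores if not np.isnan(s)]
            unm_scores = [s for s in unm_scores if not np.isnan(s)]
            if len(mod_scores) >= 2 and len(unm_scores) >= 2:
                cmp = score_comparison(mod_scores, unm_scores, test="t")
                cmp["method"] = method
                rows.append(cmp)
        if rows:
            table = pd.DataFrame(rows)
            report["disorder_means"] = table
            _write_table(table, out / "disorder_means.csv", config)

        if bg_sites_path.exists() and bg_disorder.exists():
            bg_tracks = load_disorder_csv(bg_disorder)
            bg_sites_df = pd.read_csv(bg_sites_path, comment="#")
            bg_sites = [(str(r.protein_id), int(r.position))
                        for r in bg_sites_df.itertuples(index=False)]
            mss_sites = [(r.protein_id, r.position) for r in mss.records]
            profiles = {}
            for method in sorted(set(tracks) & set(bg_tracks)):
                prof = disorder_odds_profile(
                    tracks[method], mss_sites, bg_tracks[method], bg_sites,
                    window=config.profile_halfwidth)
                profiles[method] = prof
                _write_table(
                    pd.DataFrame({"offset": prof.offsets,
                                  "log10_odds_ratio": prof.values,
                                  "ci_low": prof.ci_low,
                                  "ci_high": prof.ci_high}),
                    out / f"disorder_profile_{method}.csv", config)
            report["disorder_profiles"] = profiles
    return report
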
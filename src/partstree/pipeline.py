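"""End-to-end orchestration: simulate -> code -> tree -> chronology ->
scan -> project, with fixed seeds, per-stage logging and a checksum
manifest.

Every artifact is plain text (TSV/FASTA/BED/Newick/TOML), each stage
reads only prior-stage artifacts from the run directory, and two runs
from the same config produce bitwise-identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import io as ptio
from .align import ScoringScheme
from .chronology import ClockModel, clock_ages, node_distances
from .coding import coarse_grain_occurrence, code_abundance
from .parsimony import (branch_and_bound_search, exhaustive_search,
                        heuristic_search, lundberg_root)
from .projection import (build_relics, coevolution_correlation,
                         coevolution_table, isoacceptor_census,
                         project_oldest_helix)
from .scan import scan_queries
from .synthetic import (simulate_abundance_matrix, simulate_helix_map,
                        simulate_rrna_with_relics, simulate_trna_queries)

STAGES = ("simulate", "code", "tree", "chronology", "scan", "project")

DEFAULTS: dict = {
    # synthetic census
    "n_parts": 12, "n_proteomes": 8, "growth_rate": 3.0, "loss_prob": 0.3,
    "noise_sd": 0.2, "base_count": 100,
    # synthetic sequences
    "n_queries": 6, "n_insertions_per_query": 2, "target_length": 3000,
    "divergence": 0.1, "old_fraction": 0.8,
    # coding
    "alphabet_size": 24, "coding_scheme": "log", "occurrence": False,
    # tree search
    "search": "auto", "n_starts": 10,
    # chronology
    "origin_gy": 3.8,
    # scan
    "match": 5, "mismatch": -4, "gap_open": -12, "gap_extend": -2,
    "max_hits": 10, "p_threshold": 0.01, "n_shuffles": 200,
    # projection
    "old_cutoff": 0.3, "min_overlap": 1,
    # run
    "stages": ",".join(STAGES), "seed": 0,
}


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


def load_config(path=None, **overrides) -> dict:
    """DEFAULTS overlaid with a TOML key-value file and keyword overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        import tomllib
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _dump_config(cfg: dict, path: Path) -> None:
    lines = []
    for key, value in sorted(cfg.items()):
        if isinstance(value, bool):
            lines.append(f"{key} = {'true' if value else 'false'}")
        elif isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        else:
            lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | None = None, outdir="run",
                 log=print) -> Path:
    """Execute the configured stages in order; returns the run directory.

    A failing stage halts the run with the stage named; artifacts
    written before the failure are retained.
    """
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_config(cfg, out / "config.toml")
    stages = [s.strip() for s in str(cfg["stages"]).split(",") if s.strip()]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            globals()[f"_stage_{stage}"](cfg, out)
        except ConfigError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        log(f"stage={stage} seed={cfg['seed']} "
            f"elapsed={time.perf_counter() - t0:.2f}s")
    files = sorted(p for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.tsv")
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("file\tsha256\tbytes\n")
        for p in files:
            fh.write(f"{p.name}\t{_sha256(p)}\t{p.stat().st_size}\n")
    return out


def _require(out: Path, name: str, stage: str) -> Path:
    path = out / name
    if not path.exists():
        raise ConfigError(
            f"stage '{stage}' needs {name}, which is missing from "
            f"{out} (enable the producing stage or supply the file)")
    return path


def _stage_simulate(cfg: dict, out: Path) -> None:
    seed = int(cfg["seed"])
    matrix, truth = simulate_abundance_matrix(
        int(cfg["n_parts"]), int(cfg["n_proteomes"]),
        float(cfg["growth_rate"]), float(cfg["loss_prob"]),
        float(cfg["noise_sd"]), seed=seed,
        base_count=int(cfg["base_count"]))
    ptio.write_abundance_tsv(matrix, out / "abundance.tsv")
    with open(out / "accretion_truth.tsv", "w") as fh:
        fh.write("part\trank\tbirth_time\n")
        for rank, part in enumerate(truth.taxon_order):
            fh.write(f"{part}\t{rank}\t{truth.birth_time[part]:.6g}\n")
    queries = simulate_trna_queries(int(cfg["n_queries"]), seed=seed + 1)
    ptio.write_fasta({q.id: q.sequence for q in queries},
                     out / "trna_queries.fasta")
    ptio.write_trna_metadata_tsv(queries, out / "trna_metadata.tsv")
    target, truths = simulate_rrna_with_relics(
        queries, int(cfg["target_length"]),
        int(cfg["n_insertions_per_query"]), float(cfg["divergence"]),
        seed=seed + 2)
    ptio.write_fasta({"rRNA": target}, out / "rrna_target.fasta")
    ptio.write_truth_tsv(truths, out / "planted_truth.tsv")
    hmap = simulate_helix_map(int(cfg["target_length"]), truths,
                              float(cfg["old_fraction"]), seed=seed + 3)
    ptio.write_helix_bed(hmap, out / "helix_map.bed")


def _stage_code(cfg: dict, out: Path) -> None:
    matrix = ptio.read_abundance_tsv(_require(out, "abundance.tsv", "code"))
    if cfg["occurrence"]:
        coded = coarse_grain_occurrence(matrix)
    else:
        coded = code_abundance(matrix, int(cfg["alphabet_size"]),
                               str(cfg["coding_scheme"]))
    ptio.write_coded_tsv(coded, out / "coded.tsv")
    ptio.write_nexus_block(coded, out / "coded.nex")


def _read_coded(cfg: dict, out: Path, stage: str):
    return ptio.read_nexus_block(_require(out, "coded.nex", stage))


def _stage_tree(cfg: dict, out: Path) -> None:
    coded = _read_coded(cfg, out, "tree")
    mode = str(cfg["search"])
    if mode == "auto":
        mode = ("exhaustive" if coded.n_parts <= 8 else
                "branch_and_bound" if coded.n_parts <= 12 else "heuristic")
    if mode == "exhaustive":
        found = exhaustive_search(coded)
    elif mode == "branch_and_bound":
        found = branch_and_bound_search(coded)
    elif mode == "heuristic":
        found = [heuristic_search(coded, n_starts=int(cfg["n_starts"]),
                                  seed=int(cfg["seed"]) + 4)]
    else:
        raise ConfigError(f"unknown search mode: {mode!r}")
    with open(out / "trees_unrooted.nwk", "w") as fh:
        for tree in found:
            fh.write(tree.canonical_newick() + "\n")
    with open(out / "tree_search.log", "w") as fh:
        fh.write(f"search={mode} length={found[0].length} "
                 f"n_minimal={len(found)} seed={cfg['seed']}\n")


def _stage_chronology(cfg: dict, out: Path) -> None:
    coded = _read_coded(cfg, out, "chronology")
    newicks = _require(out, "trees_unrooted.nwk", "chronology")
    lines = [l for l in newicks.read_text().splitlines() if l.strip()]
    # reroot the first (consensus-representative) minimal tree
    tree = _unrooted_from_newick(lines[0], coded.part_ids)
    rooted = lundberg_root(tree, coded)
    ptio.write_newick(rooted, out / "tree_rooted.nwk")
    chron = clock_ages(node_distances(rooted),
                       ClockModel(float(cfg["origin_gy"])))
    ptio.write_chronology_tsv(chron, out / "chronology.tsv")


def _unrooted_from_newick(text: str, part_ids):
    from .trees import UnrootedTree
    rooted = ptio.rooted_tree_from_newick(text)
    n = rooted.n_taxa
    adj: dict[int, list[int]] = {}

    def link(a: int, b: int) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    for parent, kids in rooted.children.items():
        for k in kids:
            link(parent, k)
    # suppress any degree-2 node left by the display rooting
    for node in [x for x in list(adj) if x >= n and len(adj[x]) == 2]:
        a, b = adj.pop(node)
        adj[a][adj[a].index(node)] = b
        adj[b][adj[b].index(node)] = a
    return UnrootedTree(adj=adj, taxa=rooted.taxa)


def _scoring(cfg: dict) -> ScoringScheme:
    return ScoringScheme(match=int(cfg["match"]),
                         mismatch=int(cfg["mismatch"]),
                         gap_open=int(cfg["gap_open"]),
                         gap_extend=int(cfg["gap_extend"]))


def _read_queries(out: Path, stage: str):
    seqs = ptio.read_fasta(_require(out, "trna_queries.fasta", stage))
    return ptio.read_trna_metadata_tsv(
        _require(out, "trna_metadata.tsv", stage), seqs)


def _stage_scan(cfg: dict, out: Path) -> None:
    queries = _read_queries(out, "scan")
    target = ptio.read_fasta(_require(out, "rrna_target.fasta", "scan"))
    (target_id, target_seq), = target.items()
    hits = scan_queries(queries, target_seq, _scoring(cfg),
                        max_hits=int(cfg["max_hits"]), target_id=target_id,
                        p_threshold=float(cfg["p_threshold"]),
                        n_shuffles=int(cfg["n_shuffles"]),
                        seed=int(cfg["seed"]) + 5)
    ptio.write_hits_tsv(hits, out / "hits.tsv")
    ptio.write_hits_bed(hits, out / "hits.bed")


def _stage_project(cfg: dict, out: Path) -> None:
    hits = ptio.read_hits_tsv(_require(out, "hits.tsv", "project"))
    hmap = ptio.read_helix_bed(_require(out, "helix_map.bed", "project"))
    queries = _read_queries(out, "project")
    relics = build_relics(hits, min_overlap=int(cfg["min_overlap"]))
    for r in relics:
        project_oldest_helix(r, hmap)
    ptio.write_relics_tsv(relics, out / "relics.tsv")
    ptio.write_projection_bed(relics, hmap.target_id,
                              out / "projection.bed")
    table = coevolution_table(relics, queries,
                              old_cutoff=float(cfg["old_cutoff"]))
    table.to_csv(out / "coevolution.tsv", sep="\t", index=False)
    census = isoacceptor_census(relics, queries,
                                old_cutoff=float(cfg["old_cutoff"]))
    census.to_csv(out / "census.tsv", sep="\t", index=False)
    summary: dict = {"n_hits": len(hits), "n_relics": len(relics)}
    if len(table) >= 3 and table["nd_trna"].nunique() > 1 \
            and table["oldest_nd"].nunique() > 1:
        corr = coevolution_correlation(table, seed=int(cfg["seed"]) + 6)
        summary["spearman_rho"] = corr.rho
        summary["permutation_p"] = corr.pvalue
    (out / "coevolution_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    _plot_coevolution(table, float(cfg["old_cutoff"]),
                      out / "coevolution.png")


def _plot_coevolution(table, old_cutoff: float, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhspan(0, old_cutoff, color="mistyrose", zorder=0,
               label=f"old segments (nd <= {old_cutoff})")
    if len(table):
        for group, sub in table.groupby("group"):
            ax.scatter(sub["nd_trna"], sub["oldest_nd"], s=25,
                       label=f"group {group}")
    ax.set_xlabel("tRNA age (nd)")
    ax.set_ylabel("oldest rRNA helix age (nd) in relic")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
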
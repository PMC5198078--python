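"""Plain-text interchange: TSV censuses, FASTA, BED, NEXUS-like blocks,
Newick trees and chronology tables.

Conventions: hit and truth tables are 1-based inclusive; BED output is
0-based half-open; coded matrices render states alphanumerically.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chronology import Chronology
from .coding import parse_alphanumeric, render_alphanumeric
from .matrix import AbundanceMatrix, CodedMatrix
from .projection import HelixMap, Relic
from .scan import HomologyHit
from .synthetic import PlantedRelicTruth, TRNAQuery
from .trees import RootedTree


# --- censuses ---------------------------------------------------------------

def read_abundance_tsv(path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceMatrix.from_frame(df)


def write_abundance_tsv(m: AbundanceMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="part")


def write_coded_tsv(c: CodedMatrix, path) -> None:
    c.to_frame().to_csv(path, sep="\t", index_label="part")


def read_coded_tsv(path, alphabet_size: int = 24) -> CodedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CodedMatrix(part_ids=[str(i) for i in df.index],
                       proteome_ids=[str(col) for col in df.columns],
                       states=df.to_numpy(), alphabet_size=alphabet_size)


def write_nexus_block(c: CodedMatrix, path) -> None:
    """Minimal NEXUS-like character block (symbols line + taxon rows)."""
    symbols = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:c.alphabet_size]
    rows = render_alphanumeric(c)
    width = max(len(p) for p in c.part_ids)
    with open(path, "w") as fh:
        fh.write("#CHARACTERS\n")
        fh.write(f"DIMENSIONS NTAX={c.n_parts} NCHAR={c.n_characters};\n")
        fh.write(f'FORMAT SYMBOLS="{symbols}";\nMATRIX\n')
        for part, row in zip(c.part_ids, rows):
            fh.write(f"{part:<{width}}  {row}\n")
        fh.write(";\nEND\n")


def read_nexus_block(path) -> CodedMatrix:
    part_ids, rows, symbols = [], [], None
    in_matrix = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("FORMAT"):
            symbols = line.split('"')[1]
        elif line == "MATRIX":
            in_matrix = True
        elif line in (";", "END") or line.startswith(";"):
            in_matrix = False
        elif in_matrix and line:
            name, row = line.split()
            part_ids.append(name)
            rows.append(row)
    if symbols is None or not rows:
        raise ValueError(f"not a character block: {path}")
    proteomes = [f"char{i}" for i in range(len(rows[0]))]
    return parse_alphanumeric(rows, part_ids, proteomes,
                              alphabet_size=len(symbols))


# --- sequences --------------------------------------------------------------

def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records.items()], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_trna_metadata_tsv(queries: list[TRNAQuery], path) -> None:
    pd.DataFrame([{"id": q.id, "isoacceptor": q.isoacceptor,
                   "group": q.group, "nd_trna": q.nd_trna}
                  for q in queries]).to_csv(path, sep="\t", index=False)


def read_trna_metadata_tsv(path, sequences: dict[str, str]) -> list[TRNAQuery]:
    df = pd.read_csv(path, sep="\t")
    return [TRNAQuery(id=str(r.id), sequence=sequences[str(r.id)],
                      isoacceptor=str(r.isoacceptor), group=int(r.group),
                      nd_trna=float(r.nd_trna))
            for r in df.itertuples(index=False)]


# --- planted truth ----------------------------------------------------------

def write_truth_tsv(truths: list[PlantedRelicTruth], path) -> None:
    pd.DataFrame([{"query_id": t.query_id, "start": t.start, "end": t.end,
                   "divergence": t.divergence} for t in truths]
                 ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[PlantedRelicTruth]:
    df = pd.read_csv(path, sep="\t")
    return [PlantedRelicTruth(query_id=str(r.query_id), start=int(r.start),
                              end=int(r.end), divergence=float(r.divergence))
            for r in df.itertuples(index=False)]


# --- helix maps and hits ----------------------------------------------------

def write_helix_bed(hmap: HelixMap, path) -> None:
    with open(path, "w") as fh:
        for start, end, hid, nd in hmap.intervals:
            fh.write(f"{hmap.target_id}\t{start - 1}\t{end}\t{hid}\t{nd:.6g}\n")


def read_helix_bed(path) -> HelixMap:
    intervals, target = [], None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, hid, nd = line.split("\t")[:5]
        target = chrom
        intervals.append((int(start) + 1, int(end), hid, float(nd)))
    if target is None:
        raise ValueError(f"empty helix map: {path}")
    return HelixMap(target_id=target, intervals=intervals)


def write_hits_tsv(hits: list[HomologyHit], path) -> None:
    pd.DataFrame([{"query_id": h.query_id, "target_id": h.target_id,
                   "start": h.start, "end": h.end, "score": h.score,
                   "zscore": "" if h.zscore is None else h.zscore,
                   "pvalue": h.pvalue, "query_start": h.query_start,
                   "query_end": h.query_end} for h in hits]
                 ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        z = None if pd.isna(r.zscore) else float(r.zscore)
        out.append(HomologyHit(query_id=str(r.query_id),
                               target_id=str(r.target_id), start=int(r.start),
                               end=int(r.end), score=int(r.score), zscore=z,
                               pvalue=float(r.pvalue),
                               query_start=int(r.query_start),
                               query_end=int(r.query_end), ops=[]))
    return out


def write_hits_bed(hits: list[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.target_id}\t{h.start - 1}\t{h.end}\t{h.query_id}"
                     f"\t{h.score}\t+\n")


def _nd_rgb(nd: float) -> str:
    # red (old, nd=0) through to blue (young, nd=1) in coarse buckets
    bucket = min(int(nd * 5), 4)
    palette = ["228,26,28", "255,127,0", "255,217,47", "102,166,30",
               "55,126,184"]
    return palette[bucket]


def write_relics_tsv(relics: list[Relic], path) -> None:
    pd.DataFrame([{"start": r.start, "end": r.end,
                   "n_members": len(r.member_hits),
                   "members": ",".join(r.member_query_ids),
                   "oldest_nd": "" if r.oldest_nd is None else r.oldest_nd,
                   "helices": ",".join(h for h, _ in r.projection)}
                  for r in relics]).to_csv(path, sep="\t", index=False)


def write_projection_bed(relics: list[Relic], target_id: str, path) -> None:
    """BED9 with itemRgb coloring relics by their oldest helix nd."""
    with open(path, "w") as fh:
        for k, r in enumerate(relics):
            nd = 1.0 if r.oldest_nd is None else r.oldest_nd
            fh.write(f"{target_id}\t{r.start - 1}\t{r.end}\trelic{k}\t0\t+"
                     f"\t{r.start - 1}\t{r.end}\t{_nd_rgb(nd)}\n")


# --- chronologies and trees -------------------------------------------------

def write_chronology_tsv(chron: Chronology, path) -> None:
    chron.table.to_csv(path, sep="\t", index=False)


def read_chronology_tsv(path) -> Chronology:
    table = pd.read_csv(path, sep="\t")
    if "transferred_from" not in table.columns:
        table["transferred_from"] = None
    return Chronology(table=table)


def write_newick(tree, path, nd: dict[str, float] | None = None) -> None:
    """Write a tree as newick; optional nd annotations as leaf comments."""
    text = (tree.to_newick() if isinstance(tree, RootedTree)
            else tree.canonical_newick())
    if nd:
        for taxon, value in sorted(nd.items(), key=lambda kv: -len(kv[0])):
            text = text.replace(taxon, f"{taxon}[&nd={value:.4f}]")
    Path(path).write_text(text + "\n")


def rooted_tree_from_newick(text: str) -> RootedTree:
    """Parse a rooted binary newick into the package's rooted structure."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              rooting="force-rooted")
    taxa = sorted(leaf.taxon.label for leaf in dtree.leaf_node_iter())
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    children: dict[int, tuple[int, ...]] = {}
    counter = [n]

    def rec(node) -> int:
        if node.is_leaf():
            return index[node.taxon.label]
        nid = counter[0]
        counter[0] += 1
        kids = tuple(rec(ch) for ch in node.child_nodes())
        children[nid] = kids
        return nid

    root = rec(dtree.seed_node)
    return RootedTree(children=children, root=root, taxa=taxa)
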
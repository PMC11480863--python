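"""Readers and writers for the standard on-disk formats.

Per clonotype the inputs are an aligned FASTA (with one designated
germline/root record, default id ``naive``), a row in a tab-separated isotype
table (columns ``clonotype_id``, ``cell_id``, ``isotype_label``) and an
optional multi-newick candidate forest (one tree per line, leaf labels equal
to cell ids).  Isotype encodings (label order = ordinal) are plain text, one
label per line; the built-in ``human`` and ``mouse`` encodings may be named
instead of a file.  All trees are serialized with canonical child ordering so
outputs are byte-stable across reruns.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .infer import FitResult
from .model import (
    Clonotype,
    HUMAN_ISOTYPES,
    IsotypeAlphabet,
    LineageForest,
    LineageTree,
    MOUSE_ISOTYPES,
    TransitionMatrix,
    canonical_children,
)
from .simulate import Replicate

Node = Hashable

DEFAULT_ROOT_ID = "naive"


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------

def read_encoding(source: str) -> IsotypeAlphabet:
    """Load an isotype encoding: ``human``, ``mouse`` or a path to a text
    file with one label per line (line number = ordinal)."""
    if source == "human":
        return HUMAN_ISOTYPES
    if source == "mouse":
        return MOUSE_ISOTYPES
    path = Path(source)
    labels = [
        line.strip() for line in path.read_text().splitlines() if line.strip()
    ]
    if not labels:
        raise ValueError(f"{path}: empty encoding file")
    return IsotypeAlphabet(tuple(labels))


def write_encoding(alphabet: IsotypeAlphabet, path: Path) -> None:
    path.write_text("\n".join(alphabet.labels) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(T: LineageTree) -> str:
    """Serialize with canonical child ordering and internal node names."""
    order = canonical_children(T)

    def render(v: Node) -> str:
        if T.is_leaf(v):
            return _quote(str(v))
        inner = ",".join(render(c) for c in order[v])
        return f"({inner}){_quote(str(v))}"

    return render(T.root) + ";"


def _dendropy_to_lineage(dtree: dendropy.Tree, context: str) -> LineageTree:
    edges: List[Tuple[Node, Node]] = []
    names: Dict[int, str] = {}
    counter = [0]

    def name_of(node: dendropy.Node) -> str:
        key = id(node)
        if key not in names:
            if node.taxon is not None and node.taxon.label:
                names[key] = node.taxon.label
            elif node.label:
                names[key] = node.label
            else:
                counter[0] += 1
                names[key] = f"internal{counter[0]}"
            # dendropy replaces underscores with spaces in unquoted labels
            names[key] = names[key].replace(" ", "_")
        return names[key]

    root = dtree.seed_node
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            edges.append((name_of(node), name_of(child)))
    if not edges:
        raise ValueError(f"{context}: tree has no edges")
    return LineageTree.from_edges(edges, name_of(root))


def read_forest(path: Path, clonotype_id: str) -> LineageForest:
    """Multi-newick candidate forest, one tree per line."""
    trees: List[LineageTree] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        dtree = dendropy.Tree.get(
            data=line, schema="newick", preserve_underscores=True
        )
        trees.append(_dendropy_to_lineage(dtree, f"{path}:{i}"))
    if not trees:
        raise ValueError(f"{path}: no trees found")
    return LineageForest(clonotype_id=clonotype_id, trees=trees)


def read_tree(path: Path) -> LineageTree:
    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              preserve_underscores=True)
    return _dendropy_to_lineage(dtree, str(path))


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Validated in-memory bundle of clonotypes and optional forests."""

    alphabet: IsotypeAlphabet
    clonotypes: List[Clonotype]
    forests: Optional[List[LineageForest]] = None
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.clonotypes]
        if len(set(ids)) != len(ids):
            raise ValueError("clonotype ids are not unique")
        if self.forests is not None:
            fids = [f.clonotype_id for f in self.forests]
            if fids != ids:
                raise ValueError("forests are not keyed 1:1 to clonotypes")


def read_dataset(
    alignments_dir: str,
    isotypes_tsv: str,
    forests_dir: Optional[str] = None,
    encoding: str = "mouse",
    root_id: str = DEFAULT_ROOT_ID,
) -> Dataset:
    """Load and validate a dataset from per-clonotype FASTA alignments, an
    isotype table and (optionally) multi-newick candidate forests."""
    alphabet = read_encoding(encoding)
    iso = pd.read_csv(isotypes_tsv, sep="\t", dtype=str)
    required = {"clonotype_id", "cell_id", "isotype_label"}
    if not required <= set(iso.columns):
        raise ValueError(
            f"{isotypes_tsv}: expected columns {sorted(required)}, "
            f"got {list(iso.columns)}"
        )
    iso_map: Dict[str, Dict[str, int]] = {}
    for row in iso.itertuples(index=False):
        try:
            ordinal = alphabet.ordinal(row.isotype_label)
        except KeyError:
            raise ValueError(
                f"{isotypes_tsv}: unknown isotype label {row.isotype_label!r} "
                f"for cell {row.cell_id} (clonotype {row.clonotype_id})"
            ) from None
        iso_map.setdefault(row.clonotype_id, {})[row.cell_id] = ordinal

    clonotypes: List[Clonotype] = []
    forests: List[LineageForest] = []
    fasta_files = sorted(Path(alignments_dir).glob("*.fasta"))
    if not fasta_files:
        raise ValueError(f"{alignments_dir}: no .fasta files")
    for fasta in fasta_files:
        cid = fasta.stem
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        if root_id not in records:
            raise ValueError(f"{fasta}: missing root record {root_id!r}")
        germline = records.pop(root_id)
        if cid not in iso_map:
            raise ValueError(f"{isotypes_tsv}: no isotypes for clonotype {cid}")
        cells = iso_map[cid]
        missing = set(records) - set(cells)
        if missing:
            raise ValueError(
                f"{fasta}: cells without isotype: {sorted(missing)}"
            )
        clonotype = Clonotype(
            id=cid,
            germline=germline,
            sequences=records,
            isotypes={cell: cells[cell] for cell in records},
            alphabet=alphabet,
        )
        clonotypes.append(clonotype)
        if forests_dir is not None:
            fpath = Path(forests_dir) / f"{cid}.nwk"
            if not fpath.exists():
                raise ValueError(f"{fpath}: missing forest for clonotype {cid}")
            forest = read_forest(fpath, cid)
            for t in forest.trees:
                bad = set(t.leaves()) - set(records)
                if bad:
                    raise ValueError(
                        f"{fpath}: tree leaves not among cells: {sorted(bad)}"
                    )
                if set(t.leaves()) != set(records):
                    raise ValueError(
                        f"{fpath}: tree does not cover all cells of {cid}"
                    )
            forests.append(forest)
    return Dataset(
        alphabet=alphabet,
        clonotypes=clonotypes,
        forests=forests if forests_dir is not None else None,
        provenance={
            "alignments_dir": str(alignments_dir),
            "isotypes_tsv": str(isotypes_tsv),
            "forests_dir": str(forests_dir) if forests_dir else "",
        },
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_transitions(P: TransitionMatrix, alphabet: IsotypeAlphabet, path: Path) -> None:
    probs = np.round(P.probs, 6)
    # absorb the rounding residual into each row's largest entry so the
    # written rows sum to 1 exactly
    for s in range(probs.shape[0]):
        probs[s, np.argmax(probs[s])] += 1.0 - probs[s].sum()
    df = pd.DataFrame(probs, index=alphabet.labels, columns=alphabet.labels)
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_transitions(path: Path) -> Tuple[TransitionMatrix, IsotypeAlphabet]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TransitionMatrix(df.to_numpy(dtype=float)), IsotypeAlphabet(tuple(df.columns))


def write_tree_bundle(
    T: LineageTree, alphabet: IsotypeAlphabet, out_dir: Path, name: str
) -> None:
    """A tree as newick plus a node table (isotype ordinal+label, sequence)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{name}.nwk").write_text(tree_to_newick(T) + "\n")
    rows = []
    for v in sorted(T.nodes(), key=str):
        iso = T.beta.get(v) if T.beta else None
        rows.append(
            {
                "node": str(v),
                "isotype": iso if iso is not None else "",
                "isotype_label": alphabet.label(iso) if iso is not None else "",
                "sequence": T.alpha.get(v, "") if T.alpha else "",
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / f"{name}.nodes.tsv", sep="\t", index=False)


def read_tree_bundle(out_dir: Path, name: str) -> LineageTree:
    T = read_tree(out_dir / f"{name}.nwk")
    df = pd.read_csv(out_dir / f"{name}.nodes.tsv", sep="\t", dtype=str)
    beta: Dict[Node, int] = {}
    alpha: Dict[Node, str] = {}
    for row in df.itertuples(index=False):
        if isinstance(row.isotype, str) and row.isotype.strip():
            beta[row.node] = int(float(row.isotype))
        if isinstance(row.sequence, str) and row.sequence.strip():
            alpha[row.node] = row.sequence
    T.beta = beta or None
    T.alpha = alpha or None
    return T


def write_results(
    result: FitResult,
    alphabet: IsotypeAlphabet,
    out_dir: str,
    config: Optional[dict] = None,
) -> List[str]:
    """Write a fit: transition matrix, per-clonotype tree bundles, iteration
    log and a manifest; returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: List[str] = []
    write_transitions(result.transitions, alphabet, out / "transitions.tsv")
    manifest.append("transitions.tsv")
    trees_dir = out / "trees"
    for cid, cf in sorted(result.fits.items()):
        write_tree_bundle(cf.solutions[0].tree, alphabet, trees_dir, cid)
        manifest += [f"trees/{cid}.nwk", f"trees/{cid}.nodes.tsv"]
    with open(out / "fit_log.jsonl", "w") as fh:
        for theta, trace in result.traces.items():
            fh.write(
                json.dumps(
                    {
                        "theta": theta,
                        "objectives": trace,
                        "winner": theta == result.theta,
                    }
                )
                + "\n"
            )
    manifest.append("fit_log.jsonl")
    meta = {
        "mode": result.mode,
        "theta": result.theta,
        "objective": result.objective,
        "config": config or {},
        "files": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(meta, indent=2) + "\n")
    manifest.append("manifest.json")
    return manifest


def write_replicate(rep: Replicate, out_dir: str) -> None:
    """Write a simulated replicate as fit-ready inputs plus ground truth."""
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "forests").mkdir(exist_ok=True)
    truth_dir = out / "ground_truth"
    (truth_dir / "trees").mkdir(parents=True, exist_ok=True)
    rows = []
    for sc in rep.clonotypes:
        c = sc.clonotype
        with open(out / "alignments" / f"{c.id}.fasta", "w") as fh:
            fh.write(f">{DEFAULT_ROOT_ID}\n{c.germline}\n")
            for cell in c.cell_ids:
                fh.write(f">{cell}\n{c.sequences[cell]}\n")
        for cell in c.cell_ids:
            rows.append(
                {
                    "clonotype_id": c.id,
                    "cell_id": cell,
                    "isotype_label": c.alphabet.label(c.isotypes[cell]),
                }
            )
        with open(out / "forests" / f"{c.id}.nwk", "w") as fh:
            for t in sc.forest.trees:
                fh.write(tree_to_newick(t) + "\n")
        write_tree_bundle(sc.truth, c.alphabet, truth_dir / "trees", c.id)
    pd.DataFrame(rows).to_csv(out / "isotypes.tsv", sep="\t", index=False)
    write_encoding(rep.alphabet, out / "encoding.txt")
    write_transitions(rep.transitions, rep.alphabet, truth_dir / "transitions.tsv")
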
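"""Readers/writers and shared domain types.

Everything downstream speaks four dialects: FASTA (sequences), Newick
(time-calibrated trees, branch lengths in My), and TSV (expression tables,
ortholog maps, presence matrices, trait tables).  Sequences are plain
nucleotide strings over {A,C,G,T,N}; expression values are TPM.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

TISSUES = ("brain", "cerebellum", "heart", "kidney", "liver", "gonad")
SEXES = ("M", "F")
PRESENCE_STATES = ("present", "absent", "pseudogene_expressed", "unclear")

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (transcript, genomic scaffold or read)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(source) -> list[SequenceRecord]:
    """Read a FASTA file (path, path-like, or open text handle).

    Folded lines are joined, blank lines ignored, sequences uppercased.
    Raises :class:`FormatError` (naming the offending line) on headerless
    sequence data or on a header with no sequence.
    """
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source)
        close = True
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        if cur_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"record {cur_id!r} has no sequence (line {line_no})")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {cur_id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        if cur_id in seen:
            raise FormatError(f"duplicate sequence id {cur_id!r}")
        seen.add(cur_id)
        records.append(SequenceRecord(cur_id, seq, cur_desc))

    try:
        for i, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(i)
                head = line[1:].split(None, 1)
                if not head:
                    raise FormatError(f"empty FASTA header at line {i}")
                cur_id = head[0]
                cur_desc = head[1] if len(head) > 1 else ""
                chunks = []
            else:
                if cur_id is None:
                    raise FormatError(f"sequence data before any header at line {i}")
                chunks.append(line)
        _flush(i if records or cur_id else 0)
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Phylogeny


@dataclass
class Phylogeny:
    """Rooted, time-calibrated species tree (branch lengths in My).

    Thin wrapper over a :class:`dendropy.Tree`; unlabelled internal nodes are
    auto-named ``n<post-order index>`` so ancestral nodes are addressable.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate tip labels in tree")
        self._auto_labelled: list[dendropy.Node] = []
        for i, node in enumerate(self.tree.postorder_node_iter()):
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"n{i}"
                self._auto_labelled.append(node)
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError("tree has a branch without a length")
            if edge.length < 0:
                raise FormatError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node(self, label: str) -> dendropy.Node:
        for nd in self.tree.preorder_node_iter():
            name = nd.taxon.label if nd.taxon else nd.label
            if name == label:
                return nd
        raise KeyError(f"no node labelled {label!r}")

    def mrca(self, labels) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(l) for l in labels]
        if any(t is None for t in taxa):
            missing = [l for l, t in zip(labels, taxa) if t is None]
            raise KeyError(f"tips not in tree: {missing}")
        return self.tree.mrca(taxa=taxa)

    def depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path length for every node."""
        out: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                out[node] = 0.0
            else:
                out[node] = out[node.parent_node] + (node.edge.length or 0.0)
        return out

    def vcv(self, labels=None) -> pd.DataFrame:
        """Brownian-motion covariance: shared root-to-MRCA path length."""
        if labels is None:
            labels = self.tip_labels
        depth = self.depths()
        import numpy as np

        n = len(labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if j < i:
                    continue
                if a == b:
                    mat[i, j] = depth[self.node(a)]
                else:
                    mat[i, j] = mat[j, i] = depth[self.mrca([a, b])]
        return pd.DataFrame(mat, index=labels, columns=labels)

    def write_newick(self) -> str:
        """Newick string; auto-assigned internal labels are omitted so that
        write(read(x)) round-trips user trees without label injection."""
        saved = [(nd, nd.label) for nd in self._auto_labelled]
        for nd, _ in saved:
            nd.label = None
        try:
            s = self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        finally:
            for nd, lab in saved:
                nd.label = lab
        return s


def read_newick(text_or_path) -> Phylogeny:
    """Parse a Newick tree with branch lengths.

    Accepts a Newick string, a path, or an open handle.  Duplicate tips or
    unbalanced parentheses raise :class:`FormatError`.
    """
    if isinstance(text_or_path, (str, Path)) and not str(text_or_path).lstrip().startswith("("):
        text = Path(text_or_path).read_text()
    elif hasattr(text_or_path, "read"):
        text = text_or_path.read()
    else:
        text = str(text_or_path)
    depth = 0
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if depth < 0:
            raise FormatError("unbalanced parentheses in newick")
    if depth != 0:
        raise FormatError("unbalanced parentheses in newick")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc
    tree.is_rooted = True
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Expression tables


@dataclass
class ExpressionTable:
    """Gene-by-sample TPM matrix with per-sample metadata.

    ``values``: DataFrame genes x samples, non-negative.
    ``meta``: DataFrame indexed by sample id with columns
    species / sex / tissue / individual.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene rows: {dup}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample columns")
        if (self.values.values < 0).any():
            raise FormatError("negative expression values")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")
        need = {"species", "sex", "tissue", "individual"}
        if not need <= set(self.meta.columns):
            raise FormatError(f"metadata missing fields: {sorted(need - set(self.meta.columns))}")
        self.meta = self.meta.loc[list(self.values.columns)]
        if self.meta[["species", "sex", "tissue", "individual"]].isna().any().any():
            raise FormatError("incomplete sample metadata")
        bad_sex = set(self.meta["sex"]) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex codes: {sorted(bad_sex)}")
        bad_tissue = set(self.meta["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise FormatError(f"unknown tissues: {sorted(bad_tissue)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, mask: pd.Series) -> "ExpressionTable":
        cols = self.meta.index[mask]
        return ExpressionTable(self.values[cols].copy(), self.meta.loc[cols].copy())

    def to_tsv(self, path) -> None:
        """Single-file dialect: metadata encoded in the sample id as
        ``species|sex|tissue|individual``."""
        df = self.values.copy()
        df.columns = [
            "|".join(str(self.meta.loc[s, k]) for k in ("species", "sex", "tissue", "individual"))
            for s in df.columns
        ]
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


def read_expression_table(path, meta_path=None) -> ExpressionTable:
    """Read a gene x sample TPM TSV.

    Metadata comes either from a sidecar TSV (``meta_path``, indexed by sample
    id with species/sex/tissue/individual columns) or is parsed from sample
    ids of the form ``species|sex|tissue|individual``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate gene rows in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    else:
        rows = {}
        for col in df.columns:
            parts = str(col).split("|")
            if len(parts) != 4:
                raise FormatError(
                    f"sample id {col!r} not of form species|sex|tissue|individual "
                    "and no metadata sidecar given"
                )
            rows[col] = dict(zip(("species", "sex", "tissue", "individual"), parts))
        meta = pd.DataFrame.from_dict(rows, orient="index")
    return ExpressionTable(df, meta)


# ---------------------------------------------------------------------------
# Presence matrix


@dataclass
class PresenceMatrix:
    """Species x gene grid of conservation states.

    States: present / absent / pseudogene_expressed / unclear.
    pseudogene_expressed counts as present for conservation analyses;
    unclear is missing data.
    """

    states: pd.DataFrame  # species rows, gene columns, string states

    def __post_init__(self) -> None:
        bad = set(self.states.values.ravel()) - set(PRESENCE_STATES)
        if bad:
            raise FormatError(f"unknown presence states: {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.states.index)

    @property
    def genes(self) -> list[str]:
        return list(self.states.columns)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            out = self.states.copy()
            out.index.name = "species"
            out.to_csv(fh, sep="\t")


def read_presence_matrix(path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    return PresenceMatrix(df)


# ---------------------------------------------------------------------------
# Ortholog map / gametolog families


@dataclass
class GametologFamily:
    """One ancestral XY gene family.

    ``x_genes``/``y_genes``: per-ingroup-species transcript ids (Y may be
    absent -> missing key).  ``outgroup_genes``: per-outgroup-species autosomal
    ortholog ids.  ``retrogenes``: per-species list of (gene_id, parent)
    with parent in {"X","Y"}.  ``multicopy``: extra same-family copy ids to be
    summed into the family value, keyed by the primary gene id.
    """

    name: str
    x_genes: dict[str, str] = field(default_factory=dict)
    y_genes: dict[str, str] = field(default_factory=dict)
    outgroup_genes: dict[str, str] = field(default_factory=dict)
    retrogenes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    multicopy: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in self.y_genes:
            if sp not in self.x_genes:
                raise FormatError(
                    f"family {self.name}: Y gametolog present in {sp} without an X entry"
                )


def write_ortholog_map(families, path) -> None:
    rows = []
    for fam in families:
        for sp, g in sorted(fam.x_genes.items()):
            rows.append((fam.name, sp, "X", g))
        for sp, g in sorted(fam.y_genes.items()):
            rows.append((fam.name, sp, "Y", g))
        for sp, g in sorted(fam.outgroup_genes.items()):
            rows.append((fam.name, sp, "outgroup", g))
        for sp, lst in sorted(fam.retrogenes.items()):
            for g, parent in lst:
                rows.append((fam.name, sp, f"retro_{parent}", g))
        for primary, copies in sorted(fam.multicopy.items()):
            for g in copies:
                rows.append((fam.name, "*", f"multicopy:{primary}", g))
    pd.DataFrame(rows, columns=["family", "species", "role", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_ortholog_map(path) -> list[GametologFamily]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams: dict[str, GametologFamily] = {}
    for _, row in df.iterrows():
        fam = fams.setdefault(row["family"], GametologFamily(row["family"]))
        role, sp, gene = row["role"], row["species"], row["gene"]
        if role == "X":
            fam.x_genes[sp] = gene
        elif role == "Y":
            fam.y_genes[sp] = gene
        elif role == "outgroup":
            fam.outgroup_genes[sp] = gene
        elif role.startswith("retro_"):
            fam.retrogenes.setdefault(sp, []).append((gene, role.split("_", 1)[1]))
        elif role.startswith("multicopy:"):
            fam.multicopy.setdefault(role.split(":", 1)[1], []).append(gene)
        else:
            raise FormatError(f"unknown role {role!r} in ortholog map")
    out = []
    for fam in fams.values():
        GametologFamily.__post_init__(fam)
        out.append(fam)
    return out


def read_trait_table(path) -> pd.DataFrame:
    """Species x trait table of continuous life-history values."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(float)
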
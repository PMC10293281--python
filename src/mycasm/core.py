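"""Domain types, file I/O and tree utilities shared by every analysis stage.

The central in-memory objects are deliberately thin wrappers around the
field's standard containers: a :class:`CommunityTable` holds a pandas
DataFrame of per-sample genus counts, metadata is a validated DataFrame,
phylogenies are :class:`skbio.TreeNode` objects and distance matrices are
:class:`skbio.DistanceMatrix` objects, so every downstream stage can lean on
scikit-bio / scipy directly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("mycasm")

NA_TOKEN = "NA"

GUT_TYPES = ("ruminant", "pseudoruminant", "hindgut")
DOMESTICATION = ("domesticated", "non-domesticated")

REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "family", "gut_type", "domestication")


class CommunityTable:
    """Non-negative sample x taxon abundance matrix.

    Rows are samples, columns are taxa (genus-level OTUs). Counts may be
    reads (integers) or relative abundances; operations that need integer
    reads (Good's coverage, the null models) check explicitly.
    """

    def __init__(self, data: pd.DataFrame, allow_empty_samples: bool = False):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("community table has an empty data section")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dup}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("community table contains non-finite entries")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative entry at sample {data.index[i]!r}, taxon {data.columns[j]!r}"
            )
        row_tot = values.sum(axis=1)
        if not allow_empty_samples and (row_tot <= 0).any():
            empty = data.index[row_tot <= 0].tolist()
            raise ValueError(f"samples with zero total abundance: {empty}")
        self._data = data.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def counts(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self._data.index]

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self._data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Rows rescaled to sum to one (empty rows stay zero)."""
        tot = self._data.sum(axis=1)
        tot = tot.replace(0.0, np.nan)
        rel = self._data.div(tot, axis=0).fillna(0.0)
        return rel

    def is_integer(self) -> bool:
        v = self.counts
        return bool(np.all(np.isclose(v, np.round(v), atol=1e-9)))

    def subset(self, sample_ids=None, taxon_ids=None, allow_empty_samples=True) -> "CommunityTable":
        d = self._data
        if sample_ids is not None:
            d = d.loc[list(sample_ids)]
        if taxon_ids is not None:
            d = d[list(taxon_ids)]
        return CommunityTable(d.copy(), allow_empty_samples=allow_empty_samples)

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self._data.columns[(self._data > 0).any(axis=0)]
        return CommunityTable(self._data[keep].copy(), allow_empty_samples=True)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, CommunityTable) and self._data.equals(other._data)


@dataclass
class CoverageReport:
    """Good's coverage for one sample: C = 1 - F1/N (F1 = singleton taxa)."""

    sample_id: str
    goods_coverage: float  # NaN when the sample is empty
    n_reads: int
    n_singletons: int


# ---------------------------------------------------------------------------
# community table I/O
# ---------------------------------------------------------------------------

def read_community_table(path, fmt: str = "tsv", transpose: bool = False) -> CommunityTable:
    """Read a sample x taxon table from TSV (samples as rows) or BIOM-JSON.

    ``transpose=True`` flips a taxa-as-rows TSV on read.
    """
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed community table {path}: {exc}") from exc
        if transpose:
            df = df.T
        logger.info("read community table %s: %d samples x %d taxa", path, *df.shape)
        return CommunityTable(df)
    if fmt == "biom":
        return _read_biom_json(path)
    raise ValueError(f"unknown community table format {fmt!r}")


def _read_biom_json(path) -> CommunityTable:
    """Minimal reader for the BIOM 1.0 JSON profile (dense or sparse)."""
    with open(path) as fh:
        head = fh.read(4)
        fh.seek(0)
        if head.startswith("\x89HDF"):
            raise ValueError("HDF5 BIOM is not supported; export the JSON profile")
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed BIOM JSON {path}: {exc}") from exc
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    # BIOM stores observations (taxa) as rows; our orientation is samples-as-rows
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return CommunityTable(df)


def write_community_table(table: CommunityTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# host metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample host metadata frame (indexed by sample_id).

    Checks the required columns, uniqueness of sample ids, the categorical
    domains of gut_type/domestication, and that species -> family and
    species -> gut_type are functions.
    """
    meta = meta.copy()
    if meta.index.name != "sample_id":
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        else:
            raise ValueError("metadata requires a sample_id column")
    missing = [c for c in REQUIRED_METADATA_COLUMNS[1:] if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample_id values: {dup}")
    bad_gut = set(meta["gut_type"].dropna()) - set(GUT_TYPES) - {NA_TOKEN}
    if bad_gut:
        raise ValueError(f"unknown gut_type values: {sorted(bad_gut)}")
    bad_dom = set(meta["domestication"].dropna()) - set(DOMESTICATION) - {NA_TOKEN}
    if bad_dom:
        raise ValueError(f"unknown domestication values: {sorted(bad_dom)}")
    for target in ("family", "gut_type"):
        per_species = meta.groupby("species")[target].nunique()
        offenders = per_species[per_species > 1].index.tolist()
        if offenders:
            raise ValueError(
                f"species mapped to more than one {target}: {offenders}"
            )
    return meta


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a host metadata TSV (columns per the data contract)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata {path} missing required columns: {missing}")
    meta = validate_metadata(df)
    logger.info(
        "read metadata %s: %d samples, %d species, %d families",
        path, len(meta), meta["species"].nunique(), meta["family"].nunique(),
    )
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA_TOKEN)


def join_metadata(table: CommunityTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Metadata rows aligned to the table's samples; every sample must resolve."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return meta.loc[table.sample_ids]


# ---------------------------------------------------------------------------
# phylogenies
# ---------------------------------------------------------------------------

def read_tree(path, default_branch_length: float = 0.0) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths get a default (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"unreadable Newick in {path}: {exc}") from exc
    return _validate_tree(tree, default_branch_length)


def parse_tree(newick: str, default_branch_length: float = 0.0) -> TreeNode:
    from io import StringIO

    try:
        tree = TreeNode.read(StringIO(newick), format="newick")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"unreadable Newick: {exc}") from exc
    return _validate_tree(tree, default_branch_length)


def _validate_tree(tree: TreeNode, default_branch_length: float) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("tip labels are not unique")
    filled = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = default_branch_length
            filled += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if filled:
        warnings.warn(
            f"{filled} edges had no branch length; set to {default_branch_length}",
            stacklevel=2,
        )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix."""
    tips = [t.name for t in tree.tips()]
    if len(tips) == 1:
        return DistanceMatrix(np.zeros((1, 1)), ids=tips)
    return tree.tip_tip_distances()


def tree_height(tree: TreeNode) -> float:
    """Maximum root-to-tip path length."""
    return max(_root_to_tip(tree, t) for t in tree.tips())


def _root_to_tip(tree: TreeNode, tip: TreeNode) -> float:
    d, node = 0.0, tip
    while node is not tree:
        d += node.length or 0.0
        node = node.parent
    return d


def attach_individuals(
    species_tree: TreeNode, meta: pd.DataFrame, epsilon_scale: float = 1e-6
) -> TreeNode:
    """Per-sample host tree: samples become children of their species tip.

    Each sample in ``meta`` is attached as a pendant child of its species'
    tip with length ``epsilon_scale * tree height`` (a strictly positive
    epsilon so that proximity matrices needing inverses stay finite). The
    species tip itself stops being a tip; the returned tree's tips are
    sample ids.
    """
    tree = species_tree.copy()
    eps = epsilon_scale * max(tree_height(tree), 1.0)
    by_species = {}
    for sample, sp in meta["species"].items():
        by_species.setdefault(sp, []).append(sample)
    tips = {t.name: t for t in tree.tips()}
    missing = sorted(set(by_species) - set(tips))
    if missing:
        raise ValueError(f"species missing from host tree: {missing}")
    for sp, samples in by_species.items():
        node = tips[sp]
        node.name = f"{sp}__node"
        for sample in samples:
            node.append(TreeNode(name=str(sample), length=eps))
    # drop species tips that received no samples
    keep = {str(s) for s in meta.index}
    tree = tree.shear(keep)
    tree.prune()
    return tree


# ---------------------------------------------------------------------------
# aligned sequences (FASTA)
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Aligned sequences as a (taxa, columns) byte matrix."""

    ids: list[str]
    seqs: np.ndarray  # dtype 'S1', shape (n, L)

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate sequence ids")
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2:
            raise ValueError("alignment requires equal-length sequences")

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def slice(self, start: int, stop: int | None = None) -> "Alignment":
        return Alignment(list(self.ids), self.seqs[:, start:stop].copy())


def read_alignment(path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"unequal sequence lengths in {path}: {sorted(lengths)}")
    ids = [r.id for r in records]
    mat = np.frombuffer("".join(str(r.seq).upper() for r in records).encode(), dtype="S1")
    return Alignment(ids, mat.reshape(len(records), lengths.pop()))


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row.tobytes().decode()), id=name, description="")
        for name, row in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Good's coverage
# ---------------------------------------------------------------------------

def goods_coverage(table: CommunityTable) -> list[CoverageReport]:
    """Per-sample Good's coverage C = 1 - F1/N on integer read counts.

    Empty samples are flagged with NaN coverage rather than erroring.
    """
    if not table.is_integer():
        raise ValueError("Good's coverage requires integer read counts")
    counts = np.round(table.counts).astype(np.int64)
    reports = []
    for sample, row in zip(table.sample_ids, counts):
        n = int(row.sum())
        f1 = int((row == 1).sum())
        cov = float("nan") if n == 0 else 1.0 - f1 / n
        reports.append(CoverageReport(sample, cov, n, f1))
    return reports
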
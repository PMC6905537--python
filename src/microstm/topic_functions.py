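"""Within-topic functional potential from topics-over-OTUs distributions.

The PICRUSt-style step: within-topic OTU probabilities are mapped to
integer pseudo-counts (constant x beta, default 10000), multiplied through
a reference OTU x gene-family (KO) copy-number table, and collapsed to
KEGG pathway categories for the downstream count model.  Also builds the
matched topic x pathway table from metagenomic KO abundances for the
validation against shotgun sequencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stm_core import StmFit

logger = logging.getLogger("microstm")

__all__ = [
    "GeneContentTable", "TopicFunctionProfile",
    "topics_to_pseudocounts", "predict_functions", "collapse_pathways",
    "metagenome_topic_table",
    "read_gene_content", "read_hierarchy", "read_ko_table",
]


@dataclass
class GeneContentTable:
    """Reference OTU x gene-family copy numbers with a pathway hierarchy.

    ``hierarchy`` maps each gene (KO) id to a set of (level1, level2,
    level3) pathway triples; a KO may belong to several pathways.
    ``copy16s`` carries 16S rRNA gene copy numbers for the same reference
    OTUs (used upstream by copy-number normalization).
    """

    content: np.ndarray
    otu_ids: list[str]
    gene_ids: list[str]
    hierarchy: dict[str, set] = field(default_factory=dict)
    copy16s: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.content = np.asarray(self.content, dtype=float)
        if self.content.shape != (len(self.otu_ids), len(self.gene_ids)):
            raise ValueError("content shape does not match otu_ids x gene_ids")
        if np.any(self.content < 0):
            raise ValueError("copy numbers must be >= 0")
        for g, triples in self.hierarchy.items():
            for tr in triples:
                if len(tr) != 3 or any(not str(x) for x in tr):
                    raise ValueError(f"incomplete hierarchy triple for {g!r}: {tr}")


@dataclass
class TopicFunctionProfile:
    """Predicted functional content of each topic, at gene and pathway level."""

    pseudo_counts: np.ndarray      # K x V int
    gene_counts: np.ndarray        # K x G real
    pathway_counts: np.ndarray     # K x C int
    pathway_labels: list           # level-`level` names
    pathway_parents: dict          # level-3 name -> (level1, level2)
    constant: int
    allowed_level2: set | None


def topics_to_pseudocounts(beta: np.ndarray, constant: int = 10000) -> np.ndarray:
    """Map within-topic OTU probabilities to integer pseudo-counts.

    entry = round(constant * beta_{k,v}), half away from zero.  The large
    default constant keeps low-frequency OTUs from being floored to zero.
    """
    if constant <= 0:
        raise ValueError("constant must be > 0")
    beta = np.asarray(beta, dtype=float)
    rows = beta.sum(axis=1)
    if np.any(np.abs(rows - 1) > 1e-6):
        raise ValueError("beta rows must sum to 1")
    scaled = constant * beta
    # numpy round is half-to-even; use floor(x + 0.5) for half-away-from-zero
    return np.floor(scaled + 0.5).astype(int)


def predict_functions(pseudo: np.ndarray, gc: GeneContentTable,
                      otu_ids: list[str]) -> np.ndarray:
    """Predict per-topic gene-family content: counts x copy numbers.

    gene_counts[k, g] = sum_v pseudo[k, v] * content[v, g].  OTUs absent
    from the reference table are dropped with a logged coverage fraction.
    """
    pseudo = np.asarray(pseudo)
    if pseudo.shape[1] != len(otu_ids):
        raise ValueError("otu_ids must align with pseudo columns")
    ref = {o: i for i, o in enumerate(gc.otu_ids)}
    keep = [j for j, o in enumerate(otu_ids) if o in ref]
    if not keep:
        raise ValueError("no OTU overlap with the gene-content table")
    if len(keep) < len(otu_ids):
        frac = len(keep) / len(otu_ids)
        logger.warning(
            "predict_functions: %d/%d OTUs covered by the gene-content table "
            "(coverage %.1f%%); the rest are dropped",
            len(keep), len(otu_ids), 100 * frac)
    rows = [ref[otu_ids[j]] for j in keep]
    return pseudo[:, keep].astype(float) @ gc.content[rows, :]


def collapse_pathways(
    gene_counts: np.ndarray,
    gc: GeneContentTable,
    level: int = 3,
    allowed_level2: set | None = None,
):
    """Collapse gene-family counts to pathway categories.

    A gene contributes its full count to every pathway triple it maps to
    (multi-mapped KOs are duplicated, the common KEGG-collapse convention).
    When ``allowed_level2`` is given, triples whose level-2 name is outside
    the set are excluded.  Counts are rounded to the nearest integer for
    the downstream count model.

    Returns (K x C int matrix, labels, parents) where labels are the
    level-``level`` category names and parents maps each level-3 label to
    its (level1, level2) ancestry.
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    gene_counts = np.asarray(gene_counts, dtype=float)
    K, G = gene_counts.shape
    if G != len(gc.gene_ids):
        raise ValueError("gene_counts columns must match the gene-content table")
    if allowed_level2 is not None:
        all_l2 = {tr[1] for trs in gc.hierarchy.values() for tr in trs}
        if not set(allowed_level2) & all_l2:
            raise ValueError("allowed_level2 has no overlap with the hierarchy")
    cat_index: dict[str, int] = {}
    labels: list[str] = []
    parents: dict[str, tuple] = {}
    cols: dict[int, list] = {}
    for g, gid in enumerate(gc.gene_ids):
        for tr in gc.hierarchy.get(gid, ()):  # genes without hierarchy contribute nothing
            if allowed_level2 is not None and tr[1] not in allowed_level2:
                continue
            label = tr[level - 1]
            if label not in cat_index:
                cat_index[label] = len(labels)
                labels.append(label)
            if level == 3:
                parents[label] = (tr[0], tr[1])
            cols.setdefault(cat_index[label], []).append(g)
    C = len(labels)
    out = np.zeros((K, C))
    for c, gidx in cols.items():
        out[:, c] = gene_counts[:, gidx].sum(axis=1)
    return np.floor(out + 0.5).astype(int), labels, parents


def metagenome_topic_table(
    ko_table: pd.DataFrame,
    fit: StmFit,
    taxonomy: dict[str, tuple],
    ko_taxon_map: dict[str, tuple[str, str]],
    hierarchy: dict[str, set],
    threshold: float = 0.01,
    level: int = 3,
):
    """Build the matched topic x pathway table from metagenomic KO abundances.

    ``ko_table`` holds samples x KO-record abundances (CPM); each record
    (column) maps through ``ko_taxon_map`` to its (KO id, genus) attribution,
    as in taxon-stratified shotgun profiles.  Per topic, the OTUs with
    within-topic frequency above ``threshold`` define the topic's genus set;
    KO records attributed to those genera are retained and summed into
    level-``level`` pathway categories, rounded to integers.

    Returns (y, labels, Z) with y the (K x C) matrix and Z the per-sample
    library sizes (row sums of ko_table) for the model offset.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    genus_of_otu = {o: taxonomy[o][5] for o in fit.vocabulary if o in taxonomy}
    topic_genera = []
    any_hit = False
    for k in range(fit.K):
        hot = [fit.vocabulary[v] for v in np.nonzero(fit.beta[k] > threshold)[0]]
        genera = {genus_of_otu[o] for o in hot if o in genus_of_otu}
        genera.discard("unknown")
        if genera:
            any_hit = True
        topic_genera.append(genera)
    if not any_hit:
        raise ValueError(f"no OTU exceeds the {threshold} frequency threshold in any topic")

    records = list(ko_table.columns)
    abund = ko_table.to_numpy(dtype=float)
    Z = abund.sum(axis=1)
    rec_total = abund.sum(axis=0)   # per-record abundance summed over samples
    cat_index: dict[str, int] = {}
    labels: list[str] = []
    contrib: list[tuple[int, str, float]] = []   # (cat, genus, total)
    for j, rec in enumerate(records):
        if rec not in ko_taxon_map:
            continue
        ko, genus = ko_taxon_map[rec]
        for tr in hierarchy.get(ko, ()):
            label = tr[level - 1]
            if label not in cat_index:
                cat_index[label] = len(labels)
                labels.append(label)
            contrib.append((cat_index[label], genus, rec_total[j]))
    y = np.zeros((fit.K, len(labels)))
    for k in range(fit.K):
        genera = topic_genera[k]
        for c, genus, total in contrib:
            if genus in genera:
                y[k, c] += total
    return np.floor(y + 0.5).astype(int), labels, Z


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_gene_content(path, hierarchy_path=None, copy16s_path=None) -> GeneContentTable:
    """Tab-delimited gene-content table: rows = reference OTU ids, columns = KO ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    hierarchy = read_hierarchy(hierarchy_path) if hierarchy_path else {}
    copy16s = {}
    if copy16s_path:
        c = pd.read_csv(copy16s_path, sep="\t", header=None, dtype=str, comment="#")
        copy16s = {str(r[0]): float(r[1]) for r in c.itertuples(index=False)}
    return GeneContentTable(
        content=df.to_numpy(dtype=float),
        otu_ids=[str(o) for o in df.index],
        gene_ids=[str(g) for g in df.columns],
        hierarchy=hierarchy, copy16s=copy16s)


def read_hierarchy(path) -> dict[str, set]:
    """KO id -> 'level1;level2;level3' rows (repeated for multi-mapping)."""
    out: dict[str, set] = {}
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    for r in df.itertuples(index=False):
        parts = tuple(p.strip() for p in str(r[1]).split(";"))
        if len(parts) != 3:
            raise ValueError(f"hierarchy entry for {r[0]!r} is not level1;level2;level3")
        out.setdefault(str(r[0]), set()).add(parts)
    return out


def read_ko_table(path) -> pd.DataFrame:
    """Samples x KO abundance table (CPM), tab-delimited, first column = sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    return df


def write_gene_content(gc: GeneContentTable, path, hierarchy_path=None) -> None:
    pd.DataFrame(gc.content, index=gc.otu_ids, columns=gc.gene_ids).to_csv(
        path, sep="\t", float_format="%.10g")
    if hierarchy_path:
        with open(hierarchy_path, "w") as fh:
            for g in gc.gene_ids:
                for tr in sorted(gc.hierarchy.get(g, ())):
                    fh.write(f"{g}\t{';'.join(tr)}\n")
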
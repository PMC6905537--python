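"""Reading, validation, filtering, and normalization of OTU tables.

An OTU (operational taxonomic unit) table is a samples x OTUs matrix of
amplicon read counts, accompanied by per-sample metadata and a 7-rank
taxonomic lineage per OTU.  Counts are stored as floats because 16S rRNA
gene copy-number normalization (dividing each OTU's counts by its rRNA
operon copy number) produces non-integer values; downstream count models
round only where they must.

Supported on-disk dialects: BIOM v1 (JSON) and tab-delimited text, with
tab-delimited sidecar files for taxonomy (OTU id, semicolon-delimited
lineage) and metadata (first column = sample id).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger("microstm")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
UNKNOWN_LINEAGE = ("unknown",) * 7

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        Non-negative real matrix of shape (M, V); rows are samples.
    sample_ids, otu_ids
        Unique row / column identifiers.
    taxonomy
        Mapping OTU id -> 7-tuple lineage (kingdom ... species); missing
        entries are filled with an all-``unknown`` lineage.
    metadata
        Per-sample attribute table indexed by sample id (may be empty).
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, tuple[str, ...]] = field(default_factory=dict)
    metadata: pd.DataFrame = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.sample_ids))
        self.validate()

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        M, V = self.counts.shape
        if len(self.sample_ids) != M:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {M} rows")
        if len(self.otu_ids) != V:
            raise ValueError(f"{len(self.otu_ids)} OTU ids for {V} columns")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative values")
        # every OTU gets a lineage; fill absent ones with all-unknown
        for o in self.otu_ids:
            lin = self.taxonomy.get(o)
            if lin is None:
                self.taxonomy[o] = UNKNOWN_LINEAGE
            elif len(lin) != 7:
                lin = tuple(lin) + ("unknown",) * (7 - len(lin))
                self.taxonomy[o] = lin[:7]
        if list(self.metadata.index) != self.sample_ids:
            missing = set(self.sample_ids) - set(map(str, self.metadata.index))
            extra = set(map(str, self.metadata.index)) - set(self.sample_ids)
            if missing or extra:
                raise ValueError(
                    "metadata sample ids do not match table: "
                    f"missing={sorted(missing)} extra={sorted(extra)}"
                )
            self.metadata = self.metadata.loc[self.sample_ids]

    # convenience -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def lineage_at(self, rank: str) -> list[str]:
        """Taxon label of every OTU at `rank` (one of kingdom..species)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        i = RANKS.index(rank)
        return [self.taxonomy[o][i] for o in self.otu_ids]

    def subset(self, sample_idx=None, otu_idx=None) -> "OtuTable":
        sample_idx = np.arange(self.shape[0]) if sample_idx is None else np.asarray(sample_idx)
        otu_idx = np.arange(self.shape[1]) if otu_idx is None else np.asarray(otu_idx)
        otu_ids = [self.otu_ids[j] for j in otu_idx]
        return OtuTable(
            counts=self.counts[np.ix_(sample_idx, otu_idx)],
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            otu_ids=otu_ids,
            taxonomy={o: self.taxonomy[o] for o in otu_ids},
            metadata=self.metadata.iloc[sample_idx],
        )


@dataclass
class DesignMatrix:
    """Sample-level design matrix X (M x P) with an intercept column.

    ``column_spec`` records, per generated column, the covariate name, the
    transform that produced it and the source metadata column, so effect
    estimators can locate all columns belonging to one covariate.
    """

    X: np.ndarray
    column_spec: list[tuple[str, str, str]]  # (covariate name, transform, source column)
    sample_ids: list[str]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.sample_ids):
            raise ValueError("X rows must align with sample_ids")
        if self.X.shape[1] != len(self.column_spec):
            raise ValueError("column_spec length must equal number of columns")
        for j, (name, transform, _src) in enumerate(self.column_spec):
            col = self.X[:, j]
            if transform != "intercept" and np.ptp(col) == 0 and len(col) > 1:
                raise ValueError(f"design column {name!r} is constant")

    @property
    def P(self) -> int:
        return self.X.shape[1]

    def columns_for(self, covariate: str) -> list[int]:
        idx = [j for j, (name, _t, src) in enumerate(self.column_spec)
               if name == covariate or src == covariate]
        if not idx:
            raise ValueError(f"covariate {covariate!r} not in design matrix")
        return idx


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def parse_lineage(s: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage, tolerating GreenGenes prefixes.

    ``k__Bacteria; p__Firmicutes; ...`` and plain ``Bacteria;Firmicutes``
    both work; empty or ``x__`` fields become ``unknown``.
    """
    parts = [p.strip() for p in str(s).split(";")]
    out = []
    for p in parts[:7]:
        if "__" in p:
            p = p.split("__", 1)[1].strip()
        out.append(p if p else "unknown")
    out += ["unknown"] * (7 - len(out))
    return tuple(out)


def read_taxonomy(path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return {str(r[0]): parse_lineage(r[1]) for r in df.itertuples(index=False)}


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    return df


def read_copy_numbers(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return {str(r[0]): float(r[1]) for r in df.itertuples(index=False)}


def read_otu_table(
    path,
    format: str = "tsv",
    taxonomy_path=None,
    metadata_path=None,
    otus_in_rows: bool = True,
) -> OtuTable:
    """Read an OTU table from BIOM v1 JSON or tab-delimited text.

    The tsv dialect defaults to OTUs in rows (first column = OTU id, header
    row = sample ids); pass ``otus_in_rows=False`` for the transposed layout.
    """
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        dense = np.zeros(shape, dtype=float)
        if doc.get("matrix_type") == "dense":
            dense = np.asarray(doc["data"], dtype=float)
        else:
            for i, j, v in doc["data"]:
                dense[int(i), int(j)] = v
        counts = dense.T  # BIOM rows are observations (OTUs)
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            tax = md.get("taxonomy")
            if tax is not None:
                if isinstance(tax, list):
                    tax = ";".join(tax)
                taxonomy[str(r["id"])] = parse_lineage(tax)
    elif format == "tsv":
        # legacy QIIME tables prefix the header with '#OTU ID' and may carry
        # a '# Constructed from ...' banner above it: skip leading comment
        # lines except a tab-separated one (that's the header itself)
        skip = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "\t" not in line:
                    skip += 1
                else:
                    break
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
        if otus_in_rows:
            df = df.T
        counts = df.to_numpy(dtype=float)
        sample_ids = [str(s) for s in df.index]
        otu_ids = [str(o) for o in df.columns]
        taxonomy = {}
    else:
        raise ValueError(f"unknown format {format!r}; expected 'biom-json' or 'tsv'")

    if taxonomy_path is not None:
        taxonomy.update(read_taxonomy(taxonomy_path))
    metadata = read_metadata(metadata_path) if metadata_path is not None else None
    if metadata is not None:
        missing = [s for s in sample_ids if s not in metadata.index]
        if missing:
            raise ValueError(f"metadata missing sample ids: {missing}")
        metadata = metadata.loc[sample_ids]
    return OtuTable(counts, sample_ids, otu_ids, taxonomy, metadata)


def write_otu_table(t: OtuTable, path, otus_in_rows: bool = True) -> None:
    """Write the counts as tab-delimited text (inverse of read_otu_table)."""
    df = pd.DataFrame(t.counts, index=t.sample_ids, columns=t.otu_ids)
    if otus_in_rows:
        df = df.T
        df.index.name = "#OTU ID"
    else:
        df.index.name = "#Sample ID"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_taxonomy(t: OtuTable, path) -> None:
    with open(path, "w") as fh:
        for o in t.otu_ids:
            fh.write(f"{o}\t{';'.join(t.taxonomy[o])}\n")


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def filter_table(
    t: OtuTable,
    min_sample_reads: float = 1000,
    min_otu_total: float = 10,
    min_otu_prevalence_frac: float = 0.0,
    require_phylum: bool = True,
):
    """Quality-filter an OTU table: shallow samples first, then rare OTUs.

    Samples with fewer than ``min_sample_reads`` total reads are removed
    first; on the remaining samples an OTU is removed if its total count is
    below ``min_otu_total``, its prevalence (fraction of samples with a
    non-zero count) is below ``min_otu_prevalence_frac``, or (with
    ``require_phylum``) it lacks a known phylum-level classification.

    Returns
    -------
    (OtuTable, dict) : the filtered table and a report with the removed
    sample and OTU ids keyed by reason.
    """
    if min(min_sample_reads, min_otu_total, min_otu_prevalence_frac) < 0:
        raise ValueError("filter thresholds must be >= 0")
    totals = t.library_sizes()
    keep_s = totals >= min_sample_reads
    report = {"samples_low_reads": [s for s, k in zip(t.sample_ids, keep_s) if not k]}
    if not keep_s.any():
        raise ValueError("filtering removed every sample")
    sub = t.subset(sample_idx=np.where(keep_s)[0])

    col_tot = sub.counts.sum(axis=0)
    prev = (sub.counts > 0).mean(axis=0)
    phylum_known = np.array([sub.taxonomy[o][1].lower() != "unknown" for o in sub.otu_ids])
    low_total = col_tot < min_otu_total
    low_prev = prev < min_otu_prevalence_frac
    no_phylum = require_phylum & ~phylum_known
    drop = low_total | low_prev | no_phylum
    report["otus_low_total"] = [o for o, d in zip(sub.otu_ids, low_total) if d]
    report["otus_low_prevalence"] = [o for o, d in zip(sub.otu_ids, low_prev) if d]
    report["otus_unknown_phylum"] = [o for o, d in zip(sub.otu_ids, no_phylum) if d]
    if drop.all():
        raise ValueError("filtering removed every OTU")
    out = sub.subset(otu_idx=np.where(~drop)[0])
    return out, report


def copy_number_normalize(t: OtuTable, copy_numbers: dict[str, float]) -> OtuTable:
    """Divide each OTU's counts by its 16S rRNA gene copy number.

    OTUs absent from the map keep copy number 1 and are logged; the paper's
    closed-reference workflow guarantees coverage, real tables may not.
    """
    cn = np.ones(t.shape[1])
    missing = []
    for j, o in enumerate(t.otu_ids):
        if o in copy_numbers:
            v = float(copy_numbers[o])
            if v <= 0:
                raise ValueError(f"non-positive 16S copy number for OTU {o!r}: {v}")
            cn[j] = v
        else:
            missing.append(o)
    if missing:
        logger.warning(
            "copy_number_normalize: %d/%d OTUs missing from the copy-number "
            "table; using copy number 1 for them", len(missing), t.shape[1],
        )
    return replace_counts(t, t.counts / cn)


def replace_counts(t: OtuTable, counts: np.ndarray) -> OtuTable:
    return OtuTable(counts, list(t.sample_ids), list(t.otu_ids),
                    dict(t.taxonomy), t.metadata.copy())


def relative_abundance(t: OtuTable) -> np.ndarray:
    """Library-size-scaled counts; every row sums to 1."""
    totals = t.library_sizes()
    zero = np.where(totals <= 0)[0]
    if zero.size:
        raise ValueError(f"zero-total sample(s): {[t.sample_ids[i] for i in zero]}")
    return t.counts / totals[:, None]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _bspline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with df columns, knots at quantiles of x."""
    degree = 3
    if df < degree + 1:
        degree = max(1, df - 1)
    # build df+1 basis functions and drop the first: a full B-spline basis
    # sums to 1 and would alias the intercept column
    n_interior = df - degree
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(knots) - degree - 1
    basis = np.empty((len(x), n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        basis[:, j] = BSpline(knots, coef, degree, extrapolate=False)(x)
    basis = np.nan_to_num(basis)
    return basis[:, 1:]


def _orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial columns of degrees 1..degree (R poly() style)."""
    x = np.asarray(x, dtype=float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    Z = Q[:, 1:]
    return Z * np.sqrt(len(x))  # scale-stable, still orthogonal


def build_design_matrix(
    metadata: pd.DataFrame,
    spec: list[tuple],
    reference_levels: dict[str, str] | None = None,
) -> DesignMatrix:
    """Build the sample-level design matrix from covariate transforms.

    ``spec`` is a list of ``(column, transform)`` pairs where transform is
    ``"identity"``, ``"indicator"``, ``("bspline", df)`` or
    ``("polynomial", degree)``.  An intercept column is always prepended.
    ``bspline(df)`` emits df cubic B-spline basis columns over the observed
    range (knots at quantiles); ``polynomial(degree)`` emits ``degree``
    orthogonalized columns; ``indicator`` emits one 0/1 column per
    non-reference level (reference = lexicographically first, overridable
    via ``reference_levels``).
    """
    reference_levels = reference_levels or {}
    M = len(metadata)
    cols = [np.ones(M)]
    col_spec = [("intercept", "intercept", "")]
    for entry in spec:
        name, transform = entry
        if name not in metadata.columns:
            raise ValueError(f"unknown metadata column {name!r}")
        raw = metadata[name]
        if isinstance(transform, (tuple, list)):
            kind, arg = transform[0], int(transform[1])
        else:
            kind, arg = transform, None
        if kind in ("identity", "bspline", "polynomial"):
            x = pd.to_numeric(raw).to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"covariate {name!r} is constant")
        if kind == "identity":
            cols.append(x)
            col_spec.append((name, "identity", name))
        elif kind == "bspline":
            B = _bspline_basis(x, arg)
            for j in range(B.shape[1]):
                cols.append(B[:, j])
                col_spec.append((f"{name}:bs{j + 1}", f"bspline({arg})", name))
        elif kind == "polynomial":
            Z = _orthogonal_poly(x, arg)
            for j in range(Z.shape[1]):
                cols.append(Z[:, j])
                col_spec.append((f"{name}:poly{j + 1}", f"polynomial({arg})", name))
        elif kind == "indicator":
            levels = sorted(map(str, raw.astype(str).unique()))
            if len(levels) < 2:
                raise ValueError(f"covariate {name!r} is constant")
            ref = str(reference_levels.get(name, levels[0]))
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((raw.astype(str) == lev).to_numpy(dtype=float))
                col_spec.append((f"{name}[{lev}]", "indicator", name))
        else:
            raise ValueError(f"unknown transform {kind!r}")
    X = np.column_stack(cols)
    return DesignMatrix(X, col_spec, [str(s) for s in metadata.index])
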
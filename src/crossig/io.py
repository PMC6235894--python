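"""Typed containers and TSV/JSON readers/writers for every pipeline artifact.

All expression matrices are genes-as-rows, log2 scale; sample order is
preserved from file and never implicitly sorted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("crossig")

STANDARDIZE_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """A genes x samples log2 expression matrix with provenance tags.

    ``values`` is a DataFrame indexed by gene symbol with sample IDs as
    columns. ``standardized`` means every non-constant row has mean 0 and
    sample SD 1; constant rows are all-zero and listed in ``constant_genes``.
    ``collapsed`` means gene symbols are unique (duplicate probes resolved).
    ``sample_meta`` optionally carries per-sample provenance (source cohort,
    species) for pooled matrices.
    """

    values: pd.DataFrame
    species: str = "human"
    cohort: str = ""
    standardized: bool = False
    collapsed: bool = False
    constant_genes: tuple[str, ...] = ()
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.collapsed and self.values.index.duplicated().any():
            raise ValueError("collapsed matrix has duplicated gene IDs")
        if self.standardized and self.sample_meta is None:
            # pooled matrices (sample_meta set) are unions of per-cohort
            # standardized blocks; their row SD is (N-k)/(N-1) < 1 by design
            self._check_standardized()

    def _check_standardized(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        # all-zero rows are the standardized form of constant rows, whether
        # or not they were tagged (e.g. after a round-trip through disk)
        const = np.isin(self.values.index, list(self.constant_genes)) | (
            np.abs(arr) <= STANDARDIZE_TOL
        ).all(axis=1)
        rows = arr[~const]
        if rows.size:
            if np.abs(rows.mean(axis=1)).max() > STANDARDIZE_TOL:
                raise ValueError("standardized matrix has nonzero row means")
            if np.abs(rows.std(axis=1, ddof=1) - 1.0).max() > STANDARDIZE_TOL:
                raise ValueError("standardized matrix has row SD != 1")
        if const.any() and np.abs(arr[const]).max() > STANDARDIZE_TOL:
            raise ValueError("constant rows must be all-zero when standardized")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[present])

    def with_tags(self, **kw) -> "ExpressionMatrix":
        return replace(self, **kw)


@dataclass
class ClinicalTable:
    """Per-patient survival and covariates, indexed by sample ID.

    Required columns: ``os_months`` (non-negative), ``os_event`` ({0,1}).
    Any other column is carried as a covariate or subtype label; missing
    values stay missing (never coerced to 0).
    """

    data: pd.DataFrame

    REQUIRED = ("os_months", "os_event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        t = pd.to_numeric(self.data["os_months"], errors="raise")
        if (t < 0).any():
            bad = self.data.index[t < 0].tolist()
            raise ValueError(f"negative os_months for rows {bad}")
        ev = self.data["os_event"]
        ok = ev.isin([0, 1])
        if not ok.all():
            bad = self.data.index[~ok].tolist()
            raise ValueError(f"os_event not in {{0,1}} for rows {bad}")
        if "RS_score" in self.data.columns:
            rs = pd.to_numeric(self.data["RS_score"], errors="raise")
            out = rs.notna() & ((rs < 0) | (rs > 100))
            if out.any():
                bad = self.data.index[out].tolist()
                raise ValueError(f"RS_score outside [0,100] for rows {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def subtype_columns(self) -> list[str]:
        known = {"os_months", "os_event", "stage", "tumor_size", "afp_high"}
        return [c for c in self.data.columns if c not in known]


@dataclass(frozen=True)
class OrthologMap:
    """Mouse<->human symbol pairs; many-to-many allowed on disk."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicated ortholog pairs")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["mouse_symbol", "human_symbol"])


@dataclass(frozen=True)
class RegulatorNetwork:
    """Signed regulator->target edges: +1 means the regulator, when
    activated, moves the target up; -1 down."""

    edges: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        keys = [(r, t) for r, t, _ in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (regulator, target) pair")
        if any(s not in (1, -1) for _, _, s in self.edges):
            raise ValueError("edge sign must be +1 or -1")

    def targets_of(self, regulator: str) -> dict[str, int]:
        return {t: s for r, t, s in self.edges if r == regulator}

    @property
    def regulators(self) -> list[str]:
        seen: dict[str, None] = {}
        for r, _, _ in self.edges:
            seen.setdefault(r)
        return list(seen)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path, species: str, cohort: str, *, impute_missing: bool = False
) -> ExpressionMatrix:
    """Read a gene x sample TSV (column 1 = gene_id, header = sample IDs).

    Rows with non-numeric cells are rejected with the offending gene named,
    unless ``impute_missing`` replaces missing cells by the per-gene mean.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ValueError(f"empty expression file: {path}")
    samples = header.split("\t")[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample IDs in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        if impute_missing:
            means = num.mean(axis=1)
            num = num.apply(lambda row: row.fillna(means[row.name]), axis=1)
            logger.warning("imputed missing values in %d rows", int(bad.sum()))
            if num.isna().any(axis=1).any():
                raise ValueError("rows with all values missing cannot be imputed")
        else:
            raise ValueError(
                f"non-numeric/missing values in rows: {df.index[bad].tolist()}"
            )
    logger.info("read expression %s: shape=%s", path.name, num.shape)
    return ExpressionMatrix(values=num.astype(float), species=species, cohort=cohort)


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(data=df)


def write_clinical(c: ClinicalTable, path) -> None:
    df = c.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_labels(labels: pd.Series, path) -> None:
    out = labels.rename("class").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns (mouse, human)")
    pairs = tuple(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    )
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    omap.as_frame().to_csv(path, sep="\t", index=False)


def read_network(path) -> RegulatorNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = tuple(
        (str(r), str(t), int(s))
        for r, t, s in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    )
    return RegulatorNetwork(edges=edges)


def write_network(net: RegulatorNetwork, path) -> None:
    pd.DataFrame(net.edges, columns=["regulator", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path) -> pd.DataFrame:
    """Signature TSV: gene, t, diff, p, direction."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signature(sig: pd.DataFrame, path) -> None:
    out = sig.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_model_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_model_json(model: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(model, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort summary (baseline-characteristics table)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_cohort(
    clinical: ClinicalTable, categorical_defs: dict[str, list] | None = None
) -> pd.DataFrame:
    """Counts and integer percentages per category level.

    The denominator is all patients in the cohort; missing values are their
    own ``NA`` level, as in standard baseline-characteristics tables.
    Percentages use round-half-up.
    """
    df = clinical.data
    if df.empty:
        raise ValueError("empty clinical table")
    n = len(df)
    if categorical_defs is None:
        categorical_defs = {
            c: sorted(df[c].dropna().unique().tolist())
            for c in df.columns
            if df[c].dtype == object or df[c].nunique() <= 10
        }
    rows = []
    for var, levels in categorical_defs.items():
        col = df[var]
        for level in levels:
            count = int((col == level).sum())
            rows.append((var, str(level), count, _round_half_up(100.0 * count / n)))
        n_missing = int(col.isna().sum())
        if n_missing:
            rows.append((var, "NA", n_missing, _round_half_up(100.0 * n_missing / n)))
    return pd.DataFrame(rows, columns=["variable", "level", "count", "percent"])
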
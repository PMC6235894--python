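"""Duplicate-probe collapse, per-gene standardization, ortholog mapping and
cross-species pooling.

Standardization is always applied per dataset independently, never on the
pooled matrix; pooling requires every input to be standardized first.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthologMap

logger = logging.getLogger("crossig")


def collapse_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per gene symbol, the row with the greatest sample variance.

    Ties are broken by file order (first-listed row wins), and logged.
    """
    values = m.values
    if not values.index.duplicated().any():
        return replace(m, collapsed=True)
    var = values.var(axis=1, ddof=1).to_numpy()
    order = np.arange(len(values))
    keep: dict[str, int] = {}
    for i, gene in enumerate(values.index):
        if gene not in keep:
            keep[gene] = i
        elif var[i] > var[keep[gene]]:
            keep[gene] = i
        elif var[i] == var[keep[gene]]:
            logger.info("duplicate-probe variance tie for %s; keeping first", gene)
    idx = sorted(keep.values(), key=lambda i: order[i])
    out = values.iloc[idx]
    logger.info("collapsed %d rows to %d genes", len(values), len(out))
    return replace(m, values=out, collapsed=True)


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Transform each gene row to mean 0, sample SD (n-1) 1.

    Constant rows become all-zero and are recorded in ``constant_genes``.
    """
    if m.standardized:
        raise ValueError("matrix already standardized")
    if m.values.shape[1] < 2:
        raise ValueError("standardization needs at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0.0)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    out = (arr - mean) / safe_sd
    out[const, :] = 0.0
    if const.any():
        logger.warning("%d constant rows set to zero", int(const.sum()))
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(
        m,
        values=values,
        standardized=True,
        constant_genes=tuple(m.values.index[const]),
    )


def map_orthologs(
    mouse: ExpressionMatrix, human: ExpressionMatrix, omap: OrthologMap
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Re-index both matrices to human symbols restricted to resolved 1:1
    ortholog pairs present in both.

    Many-to-many map entries are resolved by keeping, per symbol, the partner
    whose expression row has the greatest variance (mirroring the
    duplicate-probe rule); drops are logged.
    """
    if not omap.pairs:
        raise ValueError("empty ortholog map")
    pairs = [
        (ms, hs)
        for ms, hs in omap.pairs
        if ms in mouse.values.index and hs in human.values.index
    ]
    if not pairs:
        raise ValueError("no ortholog pair present in both matrices")

    mouse_var = mouse.values.var(axis=1, ddof=1)
    human_var = human.values.var(axis=1, ddof=1)

    # resolve: for each human symbol pick the mouse partner with max variance,
    # then for each mouse symbol keep the human partner with max variance
    by_human: dict[str, str] = {}
    for ms, hs in pairs:
        cur = by_human.get(hs)
        if cur is None or mouse_var[ms] > mouse_var[cur]:
            if cur is not None:
                logger.info("ortholog %s: replacing mouse partner %s by %s", hs, cur, ms)
            by_human[hs] = ms
    by_mouse: dict[str, str] = {}
    for hs, ms in by_human.items():
        cur = by_mouse.get(ms)
        if cur is None or human_var[hs] > human_var[cur]:
            if cur is not None:
                logger.info("ortholog %s: replacing human partner %s by %s", ms, cur, hs)
            by_mouse[ms] = hs

    resolved = [(ms, hs) for ms, hs in by_mouse.items()]
    dropped = len(pairs) - len(resolved)
    if dropped:
        logger.info("ortholog mapping dropped %d non-1:1 pairs", dropped)

    mouse_rows = [ms for ms, _ in resolved]
    human_syms = [hs for _, hs in resolved]
    m_out = mouse.values.loc[mouse_rows].copy()
    m_out.index = human_syms
    h_out = human.values.loc[human_syms].copy()
    mouse2 = replace(mouse, values=m_out, collapsed=True)
    human2 = replace(human, values=h_out, collapsed=True)
    return mouse2, human2


def pool(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-wise concatenation of standardized matrices on common genes.

    Per-sample provenance (cohort, species) is kept in ``sample_meta``.
    """
    if not matrices:
        raise ValueError("nothing to pool")
    for m in matrices:
        if not m.standardized:
            raise ValueError(f"matrix {m.cohort!r} is not standardized")
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise ValueError("pooled gene intersection is empty")
    common = [g for g in matrices[0].values.index if g in set(common)]
    blocks = [m.values.loc[common] for m in matrices]
    values = pd.concat(blocks, axis=1)
    if values.columns.duplicated().any():
        raise ValueError("sample IDs collide across pooled matrices")
    meta = pd.DataFrame(
        {
            "cohort": np.concatenate(
                [[m.cohort] * m.values.shape[1] for m in matrices]
            ),
            "species": np.concatenate(
                [[m.species] * m.values.shape[1] for m in matrices]
            ),
        },
        index=values.columns,
    )
    const = tuple(
        g for m in matrices for g in m.constant_genes if g in set(common)
    )
    return ExpressionMatrix(
        values=values,
        species="pooled",
        cohort="pooled",
        standardized=True,
        collapsed=True,
        constant_genes=const,
        sample_meta=meta,
    )
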
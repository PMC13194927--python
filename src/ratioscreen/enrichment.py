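"""Gene-set over-representation analysis with directional activation scores.

A generic hypergeometric (right-tailed Fisher) enrichment over user-supplied
GMT collections, with BH adjustment across sets, plus a simplified
direction-consistency activation z-score

    z = (n_up − n_down) / sqrt(n_up + n_down)

over the differential members of each set, whose sign predicts activation
(positive) or inhibition (negative).  This is an open surrogate for
commercial pathway tools: no proprietary knowledge base and no edge-weighted
causal model — results are comparable in kind, not in content, to such
tools' outputs.

The recommended background is the set of proteins retained after detection
filtering: detection defines the testable universe.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection, ValidationError
from .dep import bh_adjust


def fisher_ora(
    input_ids,
    collection: GeneSetCollection,
    background_ids,
) -> pd.DataFrame:
    """Right-tailed Fisher (hypergeometric upper tail) ORA per gene set.

    ``input_ids`` must be a subset of ``background_ids``; each set is
    intersected with the background before testing.  Returns one row per
    set: overlap, set_size (within background), input_size, background_size,
    fisher_p = P(X ≥ overlap), and bh_p across sets.
    """
    background = set(background_ids)
    input_set = set(input_ids)
    if not background or not input_set:
        raise ValidationError("input and background must be non-empty")
    stray = input_set - background
    if stray:
        raise ValidationError(
            f"input ids not in background: {sorted(stray)[:5]}"
        )
    n_bg, n_in = len(background), len(input_set)
    rows = []
    for name in collection.names():
        members = set(collection.members(name)) & background
        overlap = len(members & input_set)
        k = len(members)
        # P(X >= overlap) for X ~ Hypergeom(N=n_bg, K=k, n=n_in)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, k, n_in)) if k else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": k,
                "input_size": n_in,
                "background_size": n_bg,
                "fisher_p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["bh_p"] = bh_adjust(table["fisher_p"].to_numpy()) if len(table) else []
    return table


def activation_z(input_directions: dict[str, int], set_members) -> float:
    """Direction-consistency z over set members present in the input.

    ``input_directions`` maps ids to ±1 (sign of the log2 fold change);
    members without a direction are excluded.  NaN when no member has a
    direction.
    """
    bad = {d for d in input_directions.values() if d not in (1, -1)}
    if bad:
        raise ValidationError(f"directions must be ±1, got {sorted(bad)}")
    signs = [input_directions[m] for m in set_members if m in input_directions]
    if not signs:
        return float("nan")
    n_up = sum(1 for s in signs if s > 0)
    n_down = len(signs) - n_up
    return (n_up - n_down) / math.sqrt(n_up + n_down)


def enrich(
    dep_records: pd.DataFrame,
    contrast: str,
    collection: GeneSetCollection,
    background_ids,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """ORA + activation z for one contrast's nominal DEPs.

    The input list is the contrast's nominal DEPs (p < p_max,
    |FC| > fc_min); directions are the signs of their log2 fold changes.
    """
    sel = dep_records[dep_records["contrast"] == contrast]
    if sel.empty:
        raise ValidationError(f"no records for contrast {contrast!r}")
    log2_thr = math.log2(fc_min)
    hits = sel[(sel["p"] < p_max) & (sel["log2fc"].abs() > log2_thr)]
    background = set(background_ids)
    input_ids = [p for p in hits["protein_id"] if p in background]
    directions = {
        r["protein_id"]: (1 if r["log2fc"] > 0 else -1)
        for _, r in hits.iterrows()
        if r["protein_id"] in background and r["log2fc"] != 0
    }
    table = fisher_ora(input_ids, collection, background)
    table["z"] = [
        activation_z(directions, collection.members(name))
        for name in table["set_name"]
    ]
    return table.sort_values("fisher_p", kind="stable").reset_index(drop=True)
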
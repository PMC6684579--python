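"""Generic over-representation analysis (ORA) and the four-process screen.

Replaces network-service enrichment with a plain hypergeometric
over-representation test against the set of proteins quantified in the run
(the only defensible background for a detection-limited proteome), plus the
"central regulator" screen: proteins of a differential set annotated to all
four supplied process sets at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_tables import AnnotationSet


def ora(
    test_set: Iterable[str],
    background: Iterable[str],
    annotations: Sequence[AnnotationSet],
    min_term_size: int = 3,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA with Benjamini-Hochberg q-values.

    Term sizes are computed after intersecting each term with the background;
    terms outside [min_term_size, max_term_size] are dropped (the count is in
    ``df.attrs['n_terms_dropped']``).  Rows are sorted by p then term_id.
    """
    test = set(test_set)
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    if not test:
        raise ValueError("test set is empty")
    stray = test - bg
    if stray:
        raise ValueError(
            f"test set must be a subset of the background; {len(stray)} stray id(s), "
            f"e.g. {sorted(stray)[:3]}"
        )

    N, n = len(bg), len(test)
    rows = []
    dropped = 0
    for ann in annotations:
        members = ann.member_ids & bg
        K = len(members)
        if K < min_term_size or K > max_term_size:
            dropped += 1
            continue
        overlap = members & test
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": ann.term_id,
                "term_name": ann.term_name,
                "overlap_count": k,
                "set_size": n,
                "term_size": K,
                "background_size": N,
                "p_value": min(p, 1.0),
                "overlap_members": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "overlap_count", "set_size", "term_size",
            "background_size", "p_value", "overlap_members",
        ],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    df.attrs["n_terms_dropped"] = dropped
    return df


def top_k_by_category(rows: pd.DataFrame, k: int = 10) -> dict[str, pd.DataFrame]:
    """Per-category top-k terms by q-value (category = term_name field).

    Ties in q are broken by term_id; categories with fewer than k terms are
    returned whole.
    """
    out: dict[str, pd.DataFrame] = {}
    if rows.empty:
        return out
    for cat, grp in rows.groupby("term_name", sort=True):
        ordered = grp.sort_values(["q_value", "term_id"], kind="mergesort")
        out[str(cat)] = ordered.head(k).reset_index(drop=True)
    return out


def central_regulators(
    de_set: Iterable[str], process_sets: Sequence[AnnotationSet]
) -> list[str]:
    """Proteins of ``de_set`` annotated to *all four* process sets, sorted."""
    if len(process_sets) != 4:
        raise ValueError(f"exactly 4 process sets are required, got {len(process_sets)}")
    result = set(de_set)
    for ann in process_sets:
        result &= ann.member_ids
    return sorted(result)
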
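"""Fold-change trend taxonomy over the three pairwise contrasts.

Given, per protein, the L-vs-H, NL-vs-H and NL-vs-L fold changes with their
composite differential-expression (DE) calls, each protein receives a set of
*independent* boolean trend flags (the published lists overlap, e.g. ITGA7 and
PLVAP appear in both the NL-characteristic and the opposite-direction group,
so the flags are deliberately not mutually exclusive):

- ``intermediate``  — DE in L vs H, with the NL level within two-fold
  (strictly less) of both the healthy and the lesional level: NL looks like a
  transitional stage between healthy and lesional skin.
- ``group_I``       — DE in NL vs H while NL is within two-fold of L:
  lesional-like change already present in non-lesional skin (candidate
  predisposing factor).
- ``group_II``      — DE in NL vs L while H and L are similar (no L-vs-H DE):
  a non-lesional-characteristic alteration.
- ``group_III``     — DE in NL vs L with the NL-vs-H and L-vs-H changes
  pointing in opposite directions relative to healthy skin (candidate
  maintenance factor of the non-lesional state).
- ``lesion_only``   — altered only in comparisons involving lesional skin
  (no NL-vs-H DE): candidate trigger/manifestation protein.
- ``unclassified_divergent`` — DE in L vs H but fitting none of the above
  patterns (e.g. a very large lesional change with NL partway but more than
  two-fold from both ends).

Thresholds follow the study's rules: the DE fold gate is inclusive
(fold change >= threshold counts as changed) while the "within two-fold"
band is strict (< threshold), so a ratio of exactly 2.0 is DE-eligible but
not intermediate-eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tables import TriContrast

SIGN_EPS = 1e-9  # |log2fc| below this counts as zero sign


@dataclass(frozen=True)
class TrendFlags:
    """Per-protein category booleans; ``None`` where a needed fc was missing."""

    protein_id: str
    de_LH: bool
    de_NLH: bool
    de_NLL: bool
    intermediate: bool | None
    group_I: bool | None
    group_II: bool | None
    group_III: bool | None
    lesion_only: bool
    unclassified_divergent: bool | None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _sign(x: float) -> int:
    if np.isnan(x) or abs(x) < SIGN_EPS:
        return 0
    return 1 if x > 0 else -1


def classify_trend(tc: TriContrast, fc_threshold: float = 2.0) -> TrendFlags:
    """Apply the trend predicates to one protein's contrast triplet.

    ``fc_threshold`` must exceed 1; T = log2(fc_threshold) is the band
    half-width on the log2 scale.  Flags that need a missing fold change are
    returned as ``None``; the DE flags are taken from the composite calls and
    are always defined.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    T = float(np.log2(fc_threshold))

    de_lh, de_nlh, de_nll = tc.lh.significant, tc.nlh.significant, tc.nll.significant
    l2_lh, l2_nlh, l2_nll = tc.lh.log2fc, tc.nlh.log2fc, tc.nll.log2fc

    def within(x: float) -> bool | None:
        return None if np.isnan(x) else bool(abs(x) < T)

    w_nlh, w_nll = within(l2_nlh), within(l2_nll)

    intermediate: bool | None
    if not de_lh:
        intermediate = False
    elif w_nlh is None or w_nll is None:
        intermediate = None
    else:
        intermediate = w_nlh and w_nll

    group_i: bool | None
    if not de_nlh:
        group_i = False
    else:
        group_i = w_nll

    group_ii = bool(de_nll and not de_lh)

    group_iii: bool | None
    if not de_nll:
        group_iii = False
    elif np.isnan(l2_nlh) or np.isnan(l2_lh):
        group_iii = None
    else:
        s_nlh, s_lh = _sign(l2_nlh), _sign(l2_lh)
        group_iii = s_nlh != 0 and s_lh != 0 and s_nlh != s_lh

    lesion_only = bool((de_lh or de_nll) and not de_nlh)

    unclassified: bool | None
    if not de_lh:
        unclassified = False
    elif intermediate is None or group_i is None or group_iii is None:
        unclassified = None
    else:
        unclassified = not intermediate and not (group_i or group_ii or group_iii)

    return TrendFlags(
        protein_id=tc.protein_id,
        de_LH=bool(de_lh),
        de_NLH=bool(de_nlh),
        de_NLL=bool(de_nll),
        intermediate=intermediate,
        group_I=group_i,
        group_II=group_ii,
        group_III=group_iii,
        lesion_only=lesion_only,
        unclassified_divergent=unclassified,
    )


class TrendClassifier:
    """Transformer-style wrapper: tri-contrast table in, flag table out.

    Stateless apart from its parameter; ``fit`` exists for pipeline
    compatibility and only validates the threshold.

    Parameters
    ----------
    fc_threshold : float, default 2.0
        Ratio defining both the DE fold gate (inclusive) and the
        "within"-band half-width (strict).
    """

    def __init__(self, fc_threshold: float = 2.0):
        self.fc_threshold = fc_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"fc_threshold": self.fc_threshold}

    def set_params(self, **params) -> "TrendClassifier":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "TrendClassifier":
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        self.n_features_in_ = 0 if X is None else len(X)
        return self

    def transform(self, X: Iterable[TriContrast]) -> pd.DataFrame:
        """Classify every TriContrast; returns a flags DataFrame (protein rows)."""
        rows = [classify_trend(tc, self.fc_threshold).as_dict() for tc in X]
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.set_index("protein_id")
        return df

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def classify_table(tri_contrasts: Sequence[TriContrast], fc_threshold: float = 2.0) -> pd.DataFrame:
    """Functional wrapper over :class:`TrendClassifier`."""
    return TrendClassifier(fc_threshold=fc_threshold).fit_transform(tri_contrasts)


def summarize_categories(flags: pd.DataFrame) -> dict:
    """Count the taxonomy categories over a flags table.

    Returns DE set sizes per contrast, the NL-vs-L up/down split among NL-vs-L
    DE proteins (requires a ``log2fc_NLL`` column when available), the
    intermediate count and its fraction of the L-vs-H DE set (NaN when that
    set is empty), per-group counts and the lesion-only count.
    """
    def count(col: str) -> int:
        if col not in flags.columns or flags.empty:
            return 0
        return int((flags[col] == True).sum())  # noqa: E712 — None counts as False

    n_de_lh = count("de_LH")
    n_int = count("intermediate")
    summary = {
        "n_proteins": int(len(flags)),
        "n_de_LH": n_de_lh,
        "n_de_NLH": count("de_NLH"),
        "n_de_NLL": count("de_NLL"),
        "n_intermediate": n_int,
        "intermediate_fraction_of_de_LH": (n_int / n_de_lh) if n_de_lh else float("nan"),
        "n_group_I": count("group_I"),
        "n_group_II": count("group_II"),
        "n_group_III": count("group_III"),
        "n_lesion_only": count("lesion_only"),
        "n_unclassified_divergent": count("unclassified_divergent"),
    }
    if "log2fc_NLL" in flags.columns and not flags.empty:
        de_nll = flags["de_NLL"] == True  # noqa: E712
        l2 = flags.loc[de_nll, "log2fc_NLL"]
        summary["n_NLL_up"] = int((l2 > 0).sum())
        summary["n_NLL_down"] = int((l2 < 0).sum())
    else:
        summary["n_NLL_up"] = 0
        summary["n_NLL_down"] = 0
    return summary
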
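"""Annotation joins, correlation summaries and sequence-function maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from sgekit.design import AmpliconDesign, VariantKey

SPLICEAI_CUTOFF = 0.2  # strict: flag requires score > 0.2


def join_annotations(results: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join external annotations onto results by canonical hgvs_c index.

    All result rows are preserved; unmatched annotation rows are ignored
    but never silently dropped from the results side.  Duplicate
    annotation keys raise, listing the offenders.  A ``splice_flag``
    column is set where ``spliceai`` exceeds the 0.2 cutoff (strictly).
    """
    dup = annotations.index[annotations.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate annotation keys: {sorted(set(dup))}")
    out = results.join(annotations, how="left")
    if "spliceai" in out.columns:
        out["splice_flag"] = out["spliceai"] > SPLICEAI_CUTOFF
        out["splice_flag"] = out["splice_flag"].fillna(False)
    else:
        out["splice_flag"] = False
    return out


def correlation_report(
    df: pd.DataFrame,
    pairs: list[tuple[str, str]],
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise-complete rank (or linear) correlations with n per pair.

    Constant columns yield an undefined correlation, flagged rather than
    silently NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be spearman or pearson")
    rows = []
    for a, b in pairs:
        sub = df[[a, b]].dropna()
        n = len(sub)
        undefined = n < 3 or sub[a].nunique() == 1 or sub[b].nunique() == 1
        if undefined:
            rho = np.nan
        elif method == "spearman":
            rho = spearmanr(sub[a], sub[b]).statistic
        else:
            rho = pearsonr(sub[a], sub[b]).statistic
        rows.append({"var1": a, "var2": b, "rho": rho, "n": n,
                     "undefined": bool(undefined)})
    return pd.DataFrame(rows)


def sequence_function_map(
    results: pd.DataFrame,
    design: AmpliconDesign,
    library: list[VariantKey],
) -> pd.DataFrame:
    """Per-position grid of categorized variant effects.

    One row per library variant: position (c.), reference and alternate
    base(s), the classifier category (or ``excluded`` with a flag), plus
    optional ClinVar / splice flags carried over from ``results``.
    Category counts reconcile exactly with the classifier output.
    """
    missing = [k.hgvs_c for k in library if k.hgvs_c not in results.index]
    if missing:
        raise ValueError(
            f"results do not cover the library: {len(missing)} missing "
            f"(first: {missing[:3]})"
        )
    rows = []
    for key in library:
        res = results.loc[key.hgvs_c]
        if key.edits:
            pos = str(key.edits[0][0])
            ref = "".join(e[1] for e in key.edits)
            alt = "".join(e[2] for e in key.edits)
        else:
            pos, ref, alt = "", "", ""
        category = res.get("category", "excluded")
        if pd.isna(category) or bool(res.get("excluded", False)):
            category = "excluded"
        rows.append({
            "hgvs_c": key.hgvs_c,
            "hgvs_p": key.hgvs_p,
            "position": pos,
            "ref": ref,
            "alt": alt,
            "category": category,
            "excluded": category == "excluded",
            "clinvar": res.get("clinvar", ""),
            "splice_flag": bool(res.get("splice_flag", False)),
        })
    grid = pd.DataFrame(rows).set_index("hgvs_c")
    if grid.index.duplicated().any():
        raise ValueError("library contains duplicate variants")
    return grid


def category_counts(grid: pd.DataFrame) -> pd.Series:
    return grid["category"].value_counts()
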
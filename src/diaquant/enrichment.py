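"""Fisher over-representation analysis against an MS-covered background.

For a foreground protein set (e.g. the proteins regulated in one
comparison, or one co-regulation cluster) and a background of all proteins
covered by the MS analysis of the same compartment, each annotation term is
tested on its 2x2 membership table.  The default is the one-sided
over-representation tail P(X >= k) of the hypergeometric distribution; a
standard two-sided Fisher test is available for combined over/under
representation.  BH correction is applied across all tested terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, IntegrityError
from .io_formats import AnnotationTable


def fisher_overrepresentation(
    foreground: set[str],
    background: set[str],
    annotation: AnnotationTable,
    sided: str = "over",
) -> pd.DataFrame:
    """Term over-representation of ``foreground`` within ``background``.

    Per term with at least one background hit the 2x2 table is
    ``[[k, n-k], [K-k, N-n-K+k]]`` with k foreground hits, n the foreground
    size, K background hits and N the background size.  ``sided="over"``
    gives the hypergeometric upper tail P(X >= k); ``sided="two"`` the
    two-sided Fisher exact p.  Fold enrichment is ``(k/n) / (K/N)``.

    Returns rows sorted by (p, term_id) with BH-adjusted p-values across
    all tested terms.

    Raises
    ------
    ConfigError
        Empty foreground or unknown ``sided``.
    IntegrityError
        Foreground not a subset of the background.
    """
    fg, bg = set(foreground), set(background)
    if not fg:
        raise ConfigError("foreground set is empty")
    if not fg <= bg:
        stray = sorted(fg - bg)[:3]
        raise IntegrityError(
            f"foreground proteins missing from background: {stray}")
    if sided not in ("over", "two"):
        raise ConfigError(f"sided must be 'over' or 'two', got {sided!r}")

    N, n = len(bg), len(fg)
    rows = []
    for term in annotation:
        members_bg = term.proteins & bg
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & fg)
        if sided == "over":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - n - K + k]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append({
            "term_id": term.term_id,
            "name": term.name,
            "k": k, "n": n, "K": K, "N": N,
            "fold_enrichment": (k / n) / (K / N),
            "p": min(p, 1.0),
        })
    out = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "n", "K", "N",
                       "fold_enrichment", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values(["p", "term_id"], kind="stable")
        out = out.reset_index(drop=True)
    else:
        out["p_adj"] = np.nan
    return out
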
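"""Downstream WGBS summaries: coverage filtering, context levels, window
tracks and stranded feature metaprofiles.

Input is per-cytosine methylation calls (MethylDackel-style dialect):
scaffold, 1-based position, strand, context (CG/CHG/CHH), methylated
read count, total read count. Two summary measures are always reported:

* weighted level — sum(methylated) / sum(total) over sites;
* site fraction — share of sites whose per-site level clears a call
  threshold (default 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
CALL_COLUMNS = ["scaffold", "position", "strand", "context", "methylated", "total"]


@dataclass
class MethylationCalls:
    """Per-cytosine context counts; ``records`` has CALL_COLUMNS."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        if len(r):
            if (r["methylated"] > r["total"]).any() or (r["methylated"] < 0).any():
                raise ValueError("need 0 <= methylated <= total")
            bad = set(r["context"].unique()) - set(CONTEXTS)
            if bad:
                raise ValueError(f"malformed contexts: {sorted(bad)}")

    def merge_strands(self) -> "MethylationCalls":
        """Collapse symmetric CG/CHG sites across strands.

        A minus-strand CG call at position p is pooled with the
        plus-strand call at p-1 (CHG at p-2); CHH is strand-specific and
        left untouched.
        """
        r = self.records.copy()
        offset = {"CG": 1, "CHG": 2}
        minus = (r["strand"] == "-") & r["context"].isin(offset)
        r.loc[minus, "position"] = r.loc[minus, "position"] - r.loc[
            minus, "context"
        ].map(offset)
        r.loc[minus, "strand"] = "+"
        merged = (
            r.groupby(["scaffold", "position", "strand", "context"], as_index=False)[
                ["methylated", "total"]
            ].sum()
        )
        return MethylationCalls(merged[CALL_COLUMNS[:4] + ["methylated", "total"]])


def filter_coverage(
    calls: MethylationCalls, min_depth: int = 3
) -> tuple[MethylationCalls, pd.DataFrame]:
    """Drop sites below ``min_depth`` total reads.

    Returns the filtered calls and a per-context before/after tally.
    """
    r = calls.records
    keep = r["total"] >= min_depth
    tally = pd.DataFrame(
        {
            "before": r["context"].value_counts(),
            "after": r.loc[keep, "context"].value_counts(),
        }
    ).fillna(0).astype(int)
    return MethylationCalls(r[keep].reset_index(drop=True)), tally


def global_context_levels(
    calls: MethylationCalls, site_call_threshold: float = 0.5
) -> pd.DataFrame:
    """Genome-wide weighted level and methylated-site fraction per context.

    Contexts without sites get NaN (missing, never zero).
    """
    rows = {}
    r = calls.records
    for ctx in CONTEXTS:
        sub = r[r["context"] == ctx]
        if sub.empty:
            rows[ctx] = {"weighted_level": np.nan, "site_fraction": np.nan, "n_sites": 0}
            continue
        level = sub["methylated"].sum() / sub["total"].sum()
        frac = float(
            ((sub["methylated"] / sub["total"]) >= site_call_threshold).mean()
        )
        rows[ctx] = {
            "weighted_level": float(level),
            "site_fraction": frac,
            "n_sites": len(sub),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def window_levels(calls: MethylationCalls, window: int = 200_000) -> pd.DataFrame:
    """Per-window per-context weighted levels over tiling windows.

    Windows without sites for a context are absent from the output.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    r = calls.records.copy()
    r["window_start"] = ((r["position"] - 1) // window) * window
    grp = (
        r.groupby(["scaffold", "window_start", "context"], as_index=False)[
            ["methylated", "total"]
        ].sum()
    )
    grp["level"] = grp["methylated"] / grp["total"]
    grp["window_end"] = grp["window_start"] + window
    return grp[["scaffold", "window_start", "window_end", "context", "level", "total"]]


def metaprofile(
    calls: MethylationCalls,
    features: pd.DataFrame,
    flank: int = 2000,
    bin_size: int = 25,
    body_bins: int = 40,
) -> pd.DataFrame:
    """Average methylation along features with fixed-bin flanks.

    Each flank is cut into ``flank // bin_size`` fixed bins (80 at the
    defaults) and the body into ``body_bins`` proportional bins; features
    on the minus strand are reversed so the axis runs 5'->3'. The value
    per bin and context is the weighted level pooled over all features.

    Output bins are indexed -80..-1 (upstream), 0..body_bins-1 (body,
    prefixed ``body``) and body_bins..body_bins+79 (downstream) via the
    ``bin`` column, with a ``zone`` column in {upstream, body, downstream}.
    """
    if flank % bin_size:
        raise ValueError("flank must be divisible by bin_size")
    n_flank = flank // bin_size
    r = calls.records
    short = features[(features["end"] - features["start"]) < body_bins]
    for _, feat in short.iterrows():
        logger.info(
            "feature %s shorter than body_bins; proportional assignment",
            feat.get("id", "?"),
        )
    out = []
    for ctx in CONTEXTS:
        sub = MethylationCalls(r[r["context"] == ctx].reset_index(drop=True))
        if sub.records.empty:
            continue
        prof = _profile_one(sub, features, flank, bin_size, body_bins)
        for b, (m, t) in enumerate(prof):
            zone = (
                "upstream"
                if b < n_flank
                else ("body" if b < n_flank + body_bins else "downstream")
            )
            out.append(
                {
                    "context": ctx,
                    "bin": b,
                    "zone": zone,
                    "level": m / t if t > 0 else np.nan,
                    "total": t,
                }
            )
    return pd.DataFrame(out)


def _profile_one(
    calls: MethylationCalls,
    features: pd.DataFrame,
    flank: int,
    bin_size: int,
    body_bins: int,
) -> np.ndarray:
    """(methylated, total) sums per oriented bin for one context."""
    n_flank = flank // bin_size
    acc = np.zeros((2 * n_flank + body_bins, 2))
    by_scaf = {
        s: g.sort_values("position") for s, g in calls.records.groupby("scaffold")
    }
    for _, feat in features.iterrows():
        tab = by_scaf.get(feat["scaffold"])
        if tab is None:
            continue
        fs, fe = int(feat["start"]), int(feat["end"])
        strand = feat.get("strand", "+")
        pos0 = tab["position"].to_numpy() - 1
        lo = np.searchsorted(pos0, fs - flank)
        hi = np.searchsorted(pos0, fe + flank)
        if lo == hi:
            continue
        p = pos0[lo:hi]
        meth = tab["methylated"].to_numpy()[lo:hi].astype(float)
        tot = tab["total"].to_numpy()[lo:hi].astype(float)
        idx = np.empty(len(p), dtype=int)
        up = p < fs
        down = p >= fe
        body = ~(up | down)
        idx[up] = (p[up] - (fs - flank)) // bin_size
        rel = (p[body] - fs) / (fe - fs)
        idx[body] = n_flank + np.minimum((rel * body_bins).astype(int), body_bins - 1)
        idx[down] = n_flank + body_bins + (p[down] - fe) // bin_size
        if strand == "-":
            idx = (2 * n_flank + body_bins - 1) - idx
        np.add.at(acc[:, 0], idx, meth)
        np.add.at(acc[:, 1], idx, tot)
    return acc
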
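"""Claim filtering and daily county-level outcome tabulation.

Hospitalization claims are kept only if the admission type is emergency or
urgent, and classified by cause from the first five ICD-10 diagnosis codes:
any I-prefix code (I00-I99) marks a cardiovascular (CVD) hospitalization,
any J-prefix code (J00-J99) a respiratory one. A claim carrying both in the
first five positions counts toward both outcome series (the two outcomes
are modeled separately, so double use does not couple the fits); the
overlap is logged so users can quantify it.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

__all__ = ["classify_claim", "tabulate"]

log = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z][0-9]")


def _valid_code(code) -> bool:
    return isinstance(code, str) and bool(_CODE_RE.match(code))


def classify_claim(admission_type: str, dx_codes) -> str:
    """Classify one claim as "CVD", "RESP", "BOTH" or "NONE".

    Planned admissions are never counted. Only the first five diagnosis
    positions, as stored, are considered (no de-duplication). Malformed
    codes are ignored with a warning.
    """
    if admission_type == "planned":
        return "NONE"
    has_cvd = has_resp = False
    for code in list(dx_codes)[:5]:
        if code is None or (isinstance(code, float) and np.isnan(code)):
            continue
        if not _valid_code(code):
            log.warning("ignoring malformed diagnosis code %r", code)
            continue
        if code[0] == "I":
            has_cvd = True
        elif code[0] == "J":
            has_resp = True
    if has_cvd and has_resp:
        return "BOTH"
    if has_cvd:
        return "CVD"
    if has_resp:
        return "RESP"
    return "NONE"


def tabulate(
    claims: pd.DataFrame,
    window: pd.DatetimeIndex,
    county_ids=None,
) -> pd.DataFrame:
    """Dense county x day grid of CVD and respiratory counts.

    `claims` needs columns claim_id, county_id, date, admission_type and
    dx1..dxN (N >= 5). Claims outside `window` are dropped (count logged);
    BOTH-classified claims increment both outcomes. The grid includes zero
    rows for every (county, day) combination.
    """
    dx_cols = sorted(
        (c for c in claims.columns if c.startswith("dx")),
        key=lambda c: int(c[2:]),
    )
    if county_ids is None:
        county_ids = sorted(claims["county_id"].unique())

    cls = claims.apply(
        lambda r: classify_claim(r["admission_type"], [r[c] for c in dx_cols]),
        axis=1,
    ) if len(claims) else pd.Series([], dtype=object)

    dates = pd.DatetimeIndex(window).normalize()
    grid = pd.DataFrame(
        0,
        index=pd.MultiIndex.from_product(
            [county_ids, dates], names=["county_id", "date"]
        ),
        columns=["cvd_count", "resp_count"],
    )
    if len(claims):
        keep = claims.assign(cls=cls.to_numpy())
        in_window = keep["date"].isin(dates)
        n_out = int((~in_window).sum())
        if n_out:
            log.info("dropped %d claims outside the study window", n_out)
        keep = keep[in_window]
        n_both = int((keep["cls"] == "BOTH").sum())
        if n_both:
            log.info("%d claims count toward both outcomes", n_both)
        for label, col in (("CVD", "cvd_count"), ("RESP", "resp_count")):
            sub = keep[keep["cls"].isin([label, "BOTH"])]
            counts = sub.groupby(["county_id", "date"]).size()
            grid.loc[counts.index, col] = counts
    return grid.reset_index()
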
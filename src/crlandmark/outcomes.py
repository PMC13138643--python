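"""Composite kidney-failure outcome derivation from long-format EHR tables.

A subject reaches the cause-1 (kidney failure) endpoint on the earlier of:

* two coded entries (diagnosis or procedure, ``code_group == 'esrd'``)
  45-365 days apart — the event date is the first entry of the earliest
  qualifying pair; or
* two *consecutive* eGFR measurements < 15 mL/min/1.73m2 at least 45 days
  apart — consecutive means adjacent in the subject's chronological eGFR
  series, so an intervening value >= 15 resets the rule; the event date is
  the first measurement of the qualifying pair (onset, not confirmation).

Death without prior kidney failure is the competing (cause-2) event at the
death date; anyone else is censored at their last recorded visit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_YEAR, RawCohort

logger = logging.getLogger(__name__)

MIN_GAP_DAYS = 45
MAX_GAP_DAYS = 365
EGFR_THRESHOLD = 15.0


def _first_coded_pair(dates, min_gap=MIN_GAP_DAYS, max_gap=MAX_GAP_DAYS):
    """Earliest first-entry date of a pair of codes min_gap..max_gap days apart."""
    dates = np.sort(np.asarray(dates))
    best = None
    for i in range(len(dates)):
        for j in range(i + 1, len(dates)):
            gap = (dates[j] - dates[i]) / np.timedelta64(1, "D")
            if min_gap <= gap <= max_gap:
                return dates[i]
            if gap > max_gap:
                break
    return best


def _first_egfr_pair(dates, values, threshold=EGFR_THRESHOLD, min_gap=MIN_GAP_DAYS):
    """First date of two adjacent-in-series eGFR < threshold, >= min_gap apart."""
    order = np.argsort(dates, kind="stable")
    dates, values = np.asarray(dates)[order], np.asarray(values)[order]
    for i in range(len(dates) - 1):
        if values[i] < threshold and values[i + 1] < threshold:
            gap = (dates[i + 1] - dates[i]) / np.timedelta64(1, "D")
            if gap >= min_gap:
                return dates[i]
    return None


def derive_esrd_outcome(cohort: RawCohort, egfr_lab="egfr", esrd_code="esrd",
                        egfr_threshold=EGFR_THRESHOLD) -> pd.DataFrame:
    """Apply the composite outcome rule to every subject.

    Returns a frame (id, event_time in years from index, cause in {0,1,2});
    subjects with no post-index observations are excluded and logged.
    """
    patients = cohort.patients.set_index("id")
    egfr = cohort.labs[cohort.labs["name"] == egfr_lab]
    codes = cohort.diagnoses[cohort.diagnoses["code_group"] == esrd_code] if len(
        cohort.diagnoses
    ) else cohort.diagnoses

    # last post-index observation date per subject, across all tables
    frames = []
    for tab in (cohort.labs, cohort.meds, cohort.diagnoses):
        if len(tab):
            frames.append(tab[["id", "date"]])
    alldates = pd.concat(frames) if frames else pd.DataFrame(columns=["id", "date"])
    alldates = alldates.merge(
        patients["index_date"], left_on="id", right_index=True
    )
    post = alldates[alldates["date"] >= alldates["index_date"]]
    last_visit = post.groupby("id")["date"].max()

    rows, excluded = [], []
    for pid, pat in patients.iterrows():
        idx = pat["index_date"]
        if pid not in last_visit.index and pd.isna(pat["death_date"]):
            excluded.append(pid)
            continue
        esrd_date = None
        sub_codes = codes[(codes["id"] == pid) & (codes["date"] >= idx)]
        if len(sub_codes) >= 2:
            esrd_date = _first_coded_pair(sub_codes["date"].to_numpy())
        sub_egfr = egfr[(egfr["id"] == pid) & (egfr["date"] >= idx)]
        if len(sub_egfr) >= 2:
            d2 = _first_egfr_pair(
                sub_egfr["date"].to_numpy(), sub_egfr["value"].to_numpy(),
                threshold=egfr_threshold,
            )
            if d2 is not None and (esrd_date is None or d2 < esrd_date):
                esrd_date = d2
        death = pat["death_date"]
        if esrd_date is not None and (pd.isna(death) or esrd_date <= death):
            end, cause = esrd_date, 1
        elif not pd.isna(death):
            end, cause = death, 2
        else:
            end, cause = last_visit[pid], 0
        t = (end - idx) / pd.Timedelta(days=1) / DAYS_PER_YEAR
        rows.append((pid, max(t, 0.5 / DAYS_PER_YEAR), cause))

    if excluded:
        logger.warning(
            "excluded %d subject(s) with no post-index observations: %s",
            len(excluded), excluded[:10],
        )
    return pd.DataFrame(rows, columns=["id", "event_time", "cause"])
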
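"""Quantification of autonomic drug-challenge heart-rate responses.

After 30 min of basal recording an autonomic agent is injected
(parasympathetic: atropine blocks / carbachol stimulates; sympathetic:
isoprenaline stimulates / atenolol blocks; NaCl vehicle control).  The
response is summarised from contiguous 10-min window means as

* the pre-injection baseline HR (mean over the 30-min basal window),
* the per-window HR expressed as % of baseline,
* the extremum HR within 2 h post injection (minimum for bradycardic agents
  carbachol/atenolol, maximum for tachycardic atropine/isoprenaline and for
  the NaCl stress response) and its time,
* the effect duration: time from injection until the curve first returns
  within +/-5 % of baseline after the extremum (0 when the curve never
  leaves the band).

The extremum direction is fixed per drug (pharmacological sign) rather than
data-driven, so noisy simulations cannot flip it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .beats import Recording
from .errors import ConfigurationError, InsufficientDataError
from .metrics import drug_windows, percent_of_baseline
from .stats import StatResult, anova_tukey, t_test

#: extremum direction per drug: "min" = bradycardic nadir, "max" = peak
DRUG_DIRECTION = {
    "carbachol": "min",
    "atenolol": "min",
    "atropine": "max",
    "isoprenaline": "max",
    "NaCl": "max",
}

RETURN_BAND_PCT = 5.0
SEARCH_WINDOW_S = 7200.0


@dataclass
class DrugResponse:
    drug: str
    baseline_hr_bpm: float
    table: pd.DataFrame  # drug-protocol window table with pct_baseline
    extremum_hr_bpm: float
    extremum_pct: float
    t_extremum_s: float
    duration_s: float


def drug_response(
    recording: Recording, t_injection_s: float, drug: str
) -> DrugResponse:
    """Quantify one drug challenge from an annotated recording."""
    if drug not in DRUG_DIRECTION:
        raise ConfigurationError(
            f"unknown drug {drug!r}; known: {sorted(DRUG_DIRECTION)}"
        )
    table = percent_of_baseline(drug_windows(recording, t_injection_s))
    baseline = float(table.loc[table["is_baseline"], "hr_bpm"].mean())
    post = table[
        (table["t_start_s"] >= t_injection_s)
        & (table["t_start_s"] < t_injection_s + SEARCH_WINDOW_S)
    ]
    if len(post) == 0:
        raise InsufficientDataError("no post-injection windows")
    if DRUG_DIRECTION[drug] == "min":
        ext = post.loc[post["hr_bpm"].idxmin()]
    else:
        ext = post.loc[post["hr_bpm"].idxmax()]
    ext_pct = float(ext["pct_baseline"])

    if abs(ext_pct - 100.0) <= RETURN_BAND_PCT:
        duration = 0.0
    else:
        after = post[post["t_start_s"] > ext["t_start_s"]]
        back = after[(after["pct_baseline"] - 100.0).abs() <= RETURN_BAND_PCT]
        if len(back):
            duration = float(back["t_start_s"].iloc[0]) - t_injection_s
        else:  # censored: effect outlasts the analysis window
            duration = float(post["t_end_s"].iloc[-1]) - t_injection_s
    return DrugResponse(
        drug=drug,
        baseline_hr_bpm=baseline,
        table=table,
        extremum_hr_bpm=float(ext["hr_bpm"]),
        extremum_pct=ext_pct,
        t_extremum_s=float(ext["t_start_s"]),
        duration_s=duration,
    )


def compare_drug_response(responses_by_group: dict[str, list[DrugResponse]]) -> StatResult:
    """Compare extremum-% responses across genotype groups.

    Two groups are compared with an unpaired Student t-test, three or more
    with one-way ANOVA + Tukey HSD.
    """
    groups = {g: [r.extremum_pct for r in rs] for g, rs in responses_by_group.items()}
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError("each group needs >= 2 animals")
    names = list(groups)
    if len(groups) == 2:
        return t_test(groups[names[0]], groups[names[1]])
    return anova_tukey(list(groups.values()), names=names)
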
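"""Reference constants for beer volatiles and feasibility verdicts.

The bundled table carries, for each key maturation compound, the human odor
threshold value (OTV) band in bottom-fermented beer and the concentration
band found in beer, both in ppm. These are literature constants shipped for
convenience and can be overridden from a user CSV with the same columns.

A method is judged *suitable for end-of-process monitoring* of a compound
when its LOD lies strictly below the OTV lower bound AND strictly below the
upper end of the process concentration band — i.e. the instrument can see
the compound before a human can, across the concentrations the process
produces. This operationalization is printed in the report so users can
audit the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .limits import LimitEstimate

SUITABILITY_RULE = (
    "suitable iff LOD < OTV lower bound and LOD < process concentration upper bound "
    "(strict inequalities)"
)

#: OTV and in-beer concentration bands (ppm) for key beer-maturation volatiles.
BEER_REFERENCE: tuple[dict, ...] = (
    {"name": "diacetyl", "otv_low": 0.10, "otv_high": 0.17, "beer_low": 0.01, "beer_high": 0.12},
    {"name": "isobutanol", "otv_low": 10.0, "otv_high": 100.0, "beer_low": 4.0, "beer_high": 24.0},
    {"name": "2-phenylethanol", "otv_low": 5.0, "otv_high": 125.0, "beer_low": 4.0, "beer_high": 51.0},
    {"name": "ethyl acetate", "otv_low": 25.0, "otv_high": 30.0, "beer_low": 8.0, "beer_high": 32.0},
    {"name": "acetaldehyde", "otv_low": 10.0, "otv_high": 15.0, "beer_low": 2.0, "beer_high": 20.0},
    {"name": "dimethyl sulfide", "otv_low": 0.09, "otv_high": 0.60, "beer_low": 0.01, "beer_high": 0.14},
)


@dataclass(frozen=True)
class ReferenceCompound:
    """OTV and process-concentration intervals (ppm) for one compound."""

    name: str
    otv_low: float
    otv_high: float
    beer_low: float
    beer_high: float

    def __post_init__(self) -> None:
        if not (0 < self.otv_low <= self.otv_high and 0 < self.beer_low <= self.beer_high):
            raise ValueError(f"{self.name}: reference intervals must be positive and ordered")


@dataclass
class FeasibilityVerdict:
    """Numeric comparison of one compound's limits against its references."""

    compound: str
    lod: float | None
    loq: float | None
    lod_below_otv_low: bool
    lod_below_beer_high: bool
    loq_below_otv_low: bool
    loq_below_beer_high: bool
    suitable: bool
    narrative: str


def beer_reference() -> list[ReferenceCompound]:
    """The bundled reference table as typed records."""
    return [ReferenceCompound(**row) for row in BEER_REFERENCE]


def load_reference(path) -> list[ReferenceCompound]:
    """User-supplied reference CSV with columns name,otv_low,otv_high,beer_low,beer_high."""
    df = pd.read_csv(path)
    return [
        ReferenceCompound(
            name=str(r["name"]), otv_low=float(r["otv_low"]), otv_high=float(r["otv_high"]),
            beer_low=float(r["beer_low"]), beer_high=float(r["beer_high"]),
        )
        for _, r in df.iterrows()
    ]


def feasibility_report(
    estimates: dict[str, tuple[LimitEstimate | float | None, LimitEstimate | float | None]],
    refs: list[ReferenceCompound] | None = None,
) -> list[FeasibilityVerdict]:
    """Compare per-compound (LOD, LOQ) pairs against the reference bands.

    ``estimates`` maps compound name → (lod, loq); values may be
    :class:`LimitEstimate` or plain ppm numbers, LOQ may be None. Compounds
    without reference data are reported with a "no reference data"
    narrative.
    """
    refs = refs if refs is not None else beer_reference()
    by_name = {r.name.lower(): r for r in refs}
    verdicts = []
    for compound, (lod, loq) in estimates.items():
        lod_v = float(lod.value) if isinstance(lod, LimitEstimate) else lod
        loq_v = float(loq.value) if isinstance(loq, LimitEstimate) else loq
        ref = by_name.get(compound.lower())
        if ref is None:
            verdicts.append(
                FeasibilityVerdict(
                    compound=compound, lod=lod_v, loq=loq_v,
                    lod_below_otv_low=False, lod_below_beer_high=False,
                    loq_below_otv_low=False, loq_below_beer_high=False,
                    suitable=False, narrative=f"{compound}: no reference data",
                )
            )
            continue
        def _below(v, bound):
            return v is not None and np.isfinite(v) and v < bound
        flags = dict(
            lod_below_otv_low=_below(lod_v, ref.otv_low),
            lod_below_beer_high=_below(lod_v, ref.beer_high),
            loq_below_otv_low=_below(loq_v, ref.otv_low),
            loq_below_beer_high=_below(loq_v, ref.beer_high),
        )
        suitable = flags["lod_below_otv_low"] and flags["lod_below_beer_high"]
        verdict = "suitable" if suitable else "not suitable"
        narrative = (
            f"{compound}: LOD {lod_v} ppm vs OTV [{ref.otv_low}, {ref.otv_high}] and "
            f"beer [{ref.beer_low}, {ref.beer_high}] ppm -> {verdict} for "
            "end-of-process monitoring"
        )
        verdicts.append(
            FeasibilityVerdict(compound=compound, lod=lod_v, loq=loq_v,
                               suitable=suitable, narrative=narrative, **flags)
        )
    return verdicts


def verdicts_to_frame(verdicts: list[FeasibilityVerdict]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in verdicts]).set_index("compound")
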
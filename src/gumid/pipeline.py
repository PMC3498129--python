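"""End-to-end identification of one sample.

Ties the stages together: contamination detection → scheme selection →
presence gate → decisional scheme → correlation matching → reconciliation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .context import ContaminationEvidence, SampleContext, detect_contamination, select_scheme
from .matching import MatchResult, best_matches, match_from_printed
from .reconcile import Interpretation, reconcile
from .refdata import CaseSample, ReplicaRecord
from .schemes import SchemeResult, run_scheme
from .sugars import MarkerThresholds, SugarProfile

__all__ = ["IdentificationReport", "identify", "identify_case"]


@dataclass(frozen=True)
class IdentificationReport:
    profile: SugarProfile
    context: SampleContext
    contamination: ContaminationEvidence
    scheme: str
    scheme_result: SchemeResult
    match_result: MatchResult | None
    interpretation: Interpretation

    @property
    def final_call(self) -> str:
        return self.interpretation.final_call


def identify(
    p: SugarProfile,
    ctx: SampleContext,
    db: Sequence[ReplicaRecord] | None = None,
    th: MarkerThresholds = MarkerThresholds(),
    match_result: MatchResult | None = None,
) -> IdentificationReport:
    """Run the full decisional model on one sample.

    ``match_result`` may be supplied directly (e.g. correlations computed
    against references outside the packaged database); otherwise it is
    computed against ``db`` when one is given.
    """
    contamination = detect_contamination(p, ctx, th)
    scheme = select_scheme(ctx, contamination)
    sr = run_scheme(p, scheme, ctx, th)
    mr = match_result
    if mr is None and db:
        try:
            mr = best_matches(p, db)
        except ValueError:
            mr = None
    interp = reconcile(sr, mr, p, ctx, th, contamination)
    return IdentificationReport(
        profile=p,
        context=ctx,
        contamination=contamination,
        scheme=scheme,
        scheme_result=sr,
        match_result=mr,
        interpretation=interp,
    )


def identify_case(
    case: CaseSample,
    th: MarkerThresholds = MarkerThresholds(),
) -> IdentificationReport:
    """Identify an encoded case sample.

    Reconciliation uses the correlation entries published for the sample
    (computed at the time against reference vectors not part of the
    packaged database) as trusted data.
    """
    return identify(
        case.profile,
        case.context,
        th=th,
        match_result=match_from_printed(case.printed_correlations),
    )
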
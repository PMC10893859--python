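"""Directional claims on the response data and the per-system scorecard.

Three observations summarize the response pattern the semantic systems must
account for:

* **A** — affiliative responses are lower when the recipient is dominant,
  and the dominance gap is at least as large for Stretched as for Bent;
* **B** — Hoot faces decrease affiliative responses for both gestures
  (aggregated over dominance);
* **C** — among dominant recipients, Bared raises affiliativeness for
  Stretched but lowers it for Bent (the originally puzzling interaction).

``check_claims`` decides each claim from cell summaries alone. The bridge
from a derived *meaning* to a predicted response *direction* is the one
step the source argues only in prose; it is made explicit here as an
ordered, user-editable rule table (:data:`DEFAULT_RULES`), each rule
carrying its rationale. ``scorecard`` combines degrees of freedom, observed
claims and rule-based predictions into the qualitative comparison of the
systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .meaning import Meaning, Ontology, close
from .pragmatics import resolve, strengthen
from .stats import CellSummary
from .systems import (
    SemanticSystem,
    Signal,
    attested_inventory,
    degrees_of_freedom,
    interpret_literal,
    interpretation_table,
)

__all__ = [
    "ObservationClaim",
    "ClaimResult",
    "check_claims",
    "PredictionRule",
    "DEFAULT_RULES",
    "predict_direction",
    "Scorecard",
    "scorecard",
    "CLAIM_DESCRIPTIONS",
]

INSUFFICIENT = "insufficient data"

CLAIM_DESCRIPTIONS = {
    "A": "affiliative responses are lower in dominants, especially for Stretched",
    "B": "Hoot faces decrease affiliative responses for both gestures",
    "C": "Bared raises affiliativeness for Stretched but lowers it for Bent "
    "(dominant recipients)",
}


@dataclass(frozen=True)
class ObservationClaim:
    id: str
    description: str


@dataclass(frozen=True)
class ClaimResult:
    id: str
    status: str  # "holds" | "fails" | "insufficient data"
    detail: str = ""

    @property
    def holds(self) -> bool:
        return self.status == "holds"


class _Cells:
    """Aggregation helper over (gesture, face, recipient_dominant) tallies."""

    def __init__(self, summaries: Iterable[CellSummary]):
        self._cells: dict[tuple, tuple[int, int]] = {}
        for s in summaries:
            if len(s.key) != 3:
                raise ValueError(
                    "check_claims expects summaries at (gesture, face, dominance) "
                    f"granularity; got key {s.key}"
                )
            if s.key in self._cells:
                raise ValueError(f"duplicate cell {s.key}")
            self._cells[s.key] = (s.n, s.n_affiliative)

    def tally(self, gesture=None, face=None, dominant=None) -> tuple[int, int]:
        n = k = 0
        for (g, f, d), (cn, ck) in self._cells.items():
            if gesture is not None and g != gesture:
                continue
            if face is not None and f != face:
                continue
            if dominant is not None and int(d) != int(dominant):
                continue
            n += cn
            k += ck
        return n, k

    def percent(self, min_n: int, **sel) -> float | None:
        n, k = self.tally(**sel)
        if n < min_n:
            return None
        return 100.0 * k / n


def check_claims(
    summaries: Iterable[CellSummary], min_n: int = 5
) -> dict[str, ClaimResult]:
    """Decide claims A, B, C from per-cell tallies.

    Marginals are aggregated from the counts. Any comparison touching a
    tally below ``min_n`` yields status "insufficient data" rather than a
    verdict; the default guard of 5 reflects how thin some cells are.
    """
    cells = _Cells(summaries)
    out: dict[str, ClaimResult] = {}

    # A: overall dominance drop, and gap(Stretched) >= gap(Bent)
    pd_dom = cells.percent(min_n, dominant=1)
    pd_non = cells.percent(min_n, dominant=0)
    gaps = {}
    for g in ("BENT", "STRETCHED"):
        lo, hi = cells.percent(min_n, gesture=g, dominant=1), cells.percent(
            min_n, gesture=g, dominant=0
        )
        gaps[g] = None if lo is None or hi is None else hi - lo
    if None in (pd_dom, pd_non) or None in gaps.values():
        out["A"] = ClaimResult("A", INSUFFICIENT)
    else:
        ok = pd_dom < pd_non and gaps["STRETCHED"] >= gaps["BENT"]
        out["A"] = ClaimResult(
            "A",
            "holds" if ok else "fails",
            f"dominant {pd_dom:.1f}% vs non-dominant {pd_non:.1f}%; "
            f"gap Stretched {gaps['STRETCHED']:.1f} vs Bent {gaps['BENT']:.1f}",
        )

    # B: Hoot < neutral within each gesture, aggregated over dominance
    b_parts = {}
    for g in ("BENT", "STRETCHED"):
        hoot = cells.percent(min_n, gesture=g, face="HOOT")
        neut = cells.percent(min_n, gesture=g, face="NEUTRAL")
        b_parts[g] = None if hoot is None or neut is None else (hoot, neut)
    if None in b_parts.values():
        out["B"] = ClaimResult("B", INSUFFICIENT)
    else:
        ok = all(hoot < neut for hoot, neut in b_parts.values())
        out["B"] = ClaimResult(
            "B",
            "holds" if ok else "fails",
            "; ".join(
                f"{g}: Hoot {h:.1f}% vs neutral {n:.1f}%"
                for g, (h, n) in b_parts.items()
            ),
        )

    # C: among dominant recipients, Bared up for Stretched, down for Bent
    sb = cells.percent(min_n, gesture="STRETCHED", face="BARED", dominant=1)
    sn = cells.percent(min_n, gesture="STRETCHED", face="NEUTRAL", dominant=1)
    bb = cells.percent(min_n, gesture="BENT", face="BARED", dominant=1)
    bn = cells.percent(min_n, gesture="BENT", face="NEUTRAL", dominant=1)
    if None in (sb, sn, bb, bn):
        out["C"] = ClaimResult("C", INSUFFICIENT)
    else:
        ok = sb > sn and bb < bn
        out["C"] = ClaimResult(
            "C",
            "holds" if ok else "fails",
            f"Stretched: Bared {sb:.1f}% vs neutral {sn:.1f}%; "
            f"Bent: Bared {bb:.1f}% vs neutral {bn:.1f}%",
        )
    return out


# ---------------------------------------------------------------------------
# Meaning -> predicted response direction
# ---------------------------------------------------------------------------

_DIRECTION_RANK = {"decrease": 0, "neutral": 1, "increase": 2}


@dataclass(frozen=True)
class PredictionRule:
    """One prose rationale made checkable.

    A rule matches when the closed meaning carries all of
    ``requires_positive``, none of ``forbids_positive``, and the dominance
    flag agrees (``dominant=None`` matches either). Rules are tried in list
    order; the first match decides the direction of the response relative
    to the same-dominance gesture-alone baseline.
    """

    id: str
    direction: str  # "increase" | "decrease" | "neutral"
    requires_positive: frozenset[str] = frozenset()
    forbids_positive: frozenset[str] = frozenset()
    dominant: bool | None = None
    rationale: str = ""

    def matches(self, positives: frozenset[str], recipient_dominant: bool) -> bool:
        if self.dominant is not None and self.dominant != recipient_dominant:
            return False
        return self.requires_positive <= positives and not (
            self.forbids_positive & positives
        )


DEFAULT_RULES: tuple[PredictionRule, ...] = (
    PredictionRule(
        id="submission-approach-to-dominant",
        direction="increase",
        requires_positive=frozenset({"APPROACH", "FEAR", "AT_ADDRESSEE"}),
        forbids_positive=frozenset({"HELP"}),
        dominant=True,
        rationale="asking to approach while signalling submission forecasts an "
        "offering, which makes approaching worthwhile",
    ),
    PredictionRule(
        id="begging-under-clear-dominance",
        direction="decrease",
        requires_positive=frozenset({"APPROACH", "HELP", "FEAR"}),
        dominant=True,
        rationale="if helping asserts dominance, it becomes unnecessary (costly) "
        "once dominance is already signalled",
    ),
    PredictionRule(
        id="antagonism-is-counterproductive",
        direction="decrease",
        requires_positive=frozenset({"ANTAGONISM"}),
        rationale="signalling antagonism discourages an affiliative response "
        "regardless of the gesture",
    ),
    PredictionRule(
        id="approach-request-to-dominant",
        direction="decrease",
        requires_positive=frozenset({"APPROACH"}),
        forbids_positive=frozenset({"HELP"}),
        dominant=True,
        rationale="asking a dominant to approach is somewhat doomed to fail",
    ),
    PredictionRule(
        id="begging-from-dominant",
        direction="neutral",
        requires_positive=frozenset({"APPROACH", "HELP"}),
        dominant=True,
        rationale="begging for help from a dominant may be met with success, as "
        "the dominant is in a position to provide it",
    ),
)


def predict_direction(
    m: Meaning,
    recipient_dominant: bool,
    rules: Sequence[PredictionRule] = DEFAULT_RULES,
    ontology: Ontology | None = None,
) -> tuple[str, str | None]:
    """First-matching-rule direction for a meaning; ``neutral`` if none match.

    Returns ``(direction, rule_id)`` so every decision is traceable.
    Matching is on the closure of the meaning when an ontology is supplied,
    so defined atoms (submission) trigger rules phrased over their parts.
    """
    positives = close(m, ontology).positives() if ontology is not None else m.positives()
    for rule in rules:
        if rule.matches(positives, bool(recipient_dominant)):
            return rule.direction, rule.id
    return "neutral", None


# ---------------------------------------------------------------------------
# Scorecard
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SystemScore:
    system_id: str
    df: int
    claims: Mapping[str, str]  # claim id -> "accounted" | "not accounted" | INSUFFICIENT
    rationale: Mapping[str, str]


@dataclass(frozen=True)
class Scorecard:
    rows: tuple[SystemScore, ...]
    observed: Mapping[str, ClaimResult]

    def to_dataframe(self) -> pd.DataFrame:
        out = []
        for r in self.rows:
            row = {"system": r.system_id, "df": r.df}
            for cid in sorted(r.claims):
                row[f"claim_{cid}"] = r.claims[cid]
            out.append(row)
        return pd.DataFrame(out)

    def to_text(self) -> str:
        lines = ["Qualitative comparison of the systems", "=" * 38]
        for cid, res in sorted(self.observed.items()):
            lines.append(f"observed {cid} ({CLAIM_DESCRIPTIONS[cid]}): {res.status}")
            if res.detail:
                lines.append(f"    {res.detail}")
        lines.append("")
        for r in self.rows:
            lines.append(f"{r.system_id}: {r.df} degrees of freedom")
            for cid in sorted(r.claims):
                lines.append(f"  {cid}: {r.claims[cid]} — {r.rationale[cid]}")
        return "\n".join(lines)


def _final_meaning(sys: SemanticSystem, signal: Signal, attested) -> Meaning:
    if sys.enrichment == "informativity":
        m, _ = strengthen(signal, sys, attested)
        m, _ = resolve(m, sys.ontology)
        return m
    return interpret_literal(signal, sys)


def scorecard(
    systems: Sequence[SemanticSystem],
    summaries: Iterable[CellSummary],
    rules: Sequence[PredictionRule] = DEFAULT_RULES,
    attested: Iterable[Signal] | None = None,
    min_n: int = 5,
) -> Scorecard:
    """Degrees of freedom plus per-claim accounting for each system.

    A claim is *accounted* by a system when it holds in the summaries and
    the directions the system's meanings predict (through the rule table)
    agree with it:

    * A — the gesture-alone meanings predict the dominance asymmetry
      (Stretched to a dominant: decrease; Bent strictly less negative);
    * B — both gesture+Hoot meanings predict a decrease at either
      dominance level;
    * C — Stretched+Bared predicts an increase and Bent+Bared a decrease
      for dominant recipients.
    """
    attested = frozenset(attested) if attested is not None else attested_inventory()
    observed = check_claims(summaries, min_n=min_n)
    summaries = list(summaries)
    rows = []
    for sys in systems:
        df = degrees_of_freedom(sys, attested)
        meanings = {s: _final_meaning(sys, s, attested) for s in attested}
        o = sys.ontology
        claims: dict[str, str] = {}
        rationale: dict[str, str] = {}

        def predicted(gesture: str, face: str, dominant: bool) -> str:
            sig = Signal(gesture, face)
            d, rid = predict_direction(meanings[sig], dominant, rules, o)
            return d

        # A
        pred_s = predicted("STRETCHED", "NEUTRAL", True)
        pred_b = predicted("BENT", "NEUTRAL", True)
        pred_ok_a = (
            pred_s == "decrease"
            and _DIRECTION_RANK[pred_b] > _DIRECTION_RANK[pred_s]
        )
        rationale["A"] = (
            f"predicted for dominant recipients: Stretched {pred_s}, Bent {pred_b}"
        )
        # B
        preds_b = {
            (g, dom): predicted(g, "HOOT", dom)
            for g in ("BENT", "STRETCHED")
            for dom in (True, False)
        }
        pred_ok_b = all(d == "decrease" for d in preds_b.values())
        rationale["B"] = "predicted Hoot effect: " + ", ".join(
            f"{g}/{'dom' if dom else 'non-dom'} {d}" for (g, dom), d in sorted(preds_b.items())
        )
        # C
        pred_sb = predicted("STRETCHED", "BARED", True)
        pred_bb = predicted("BENT", "BARED", True)
        pred_ok_c = pred_sb == "increase" and pred_bb == "decrease"
        rationale["C"] = (
            f"predicted for dominant recipients: Stretched+Bared {pred_sb}, "
            f"Bent+Bared {pred_bb}"
        )

        for cid, pred_ok in (("A", pred_ok_a), ("B", pred_ok_b), ("C", pred_ok_c)):
            if observed[cid].status == INSUFFICIENT:
                claims[cid] = INSUFFICIENT
            elif observed[cid].holds and pred_ok:
                claims[cid] = "accounted"
            else:
                claims[cid] = "not accounted"
        rows.append(SystemScore(sys.id, df, claims, rationale))
    return Scorecard(tuple(rows), observed)
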
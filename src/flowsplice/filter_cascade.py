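"""Event-selection cascade for flow-regulated cassette exons.

Nested rules progressively narrow the set of skipped exons:

1. *flow-regulated*: Bayes factor above threshold in two independent
   low-vs-high-flow comparisons, consistent direction, and a change larger
   than ``replicate_ratio`` times the between-replicate (high-flow vs
   high-flow) difference;
2. *endothelial*: at least half of the in vivo flow-induced change is
   recapitulated in cultured purified endothelial cells (inclusive bound);
3. *platelet-regulated*: platelet depletion reverts the flow-induced change
   by more than half in both of two independent comparisons (strict bound);
4. *in-vitro-factor-regulated*: adding platelets, macrophages and plasma to
   cultured endothelial cells reproduces more than half of the flow-induced
   change (strict bound).

A fifth, separately reported rule labels events whose inclusion responds to
endothelial Rbfox2 deletion, as moving either with ("same") or against
("reverted") the flow-induced direction.

Each rule returns both the retained event set and a per-event audit table
stating which clause passed or failed with the values used, so the selection
funnel is fully reconstructable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .splice_events import ComparisonRecord, ValidationError

#: comparison roles the cascade needs, mapped in config to comparison_ids
ROLE_NAMES = (
    "flow_1",
    "flow_2",
    "replicate_control",
    "endothelial",
    "platelet_igg_1",
    "platelet_igg_2",
    "platelet_depl_1",
    "platelet_depl_2",
    "in_vitro",
    "rbfox2_invivo_low_1",
    "rbfox2_invivo_low_2",
    "rbfox2_invivo_high",
    "rbfox2_invitro",
)

RULES = ("flow", "endothelial", "platelet", "in_vitro", "rbfox2")


@dataclass
class SelectionConfig:
    """Thresholds of the selection cascade.

    ``bf_threshold`` and ``replicate_ratio`` are strict (>), matching the
    wording "BF > 5" / "> 2 x"; ``recapitulation_min`` is inclusive for the
    endothelial rule ("at least 50%") and strict for the in-vitro-factor rule
    ("> 50%"); ``reversion_min`` is strict.
    """

    bf_threshold: float = 5.0
    replicate_ratio: float = 2.0
    recapitulation_min: float = 0.5
    reversion_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("bf_threshold", "replicate_ratio", "recapitulation_min", "reversion_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"SelectionConfig.{name} must be > 0")


@dataclass
class RuleResult:
    rule: str
    retained: set[str]
    audit: pd.DataFrame  # one row per candidate event

    def __contains__(self, event_id: str) -> bool:
        return event_id in self.retained


@dataclass
class SelectionReport:
    """Retained sets and audits for every rule, plus flow directions."""

    flow: RuleResult
    endothelial: RuleResult
    platelet: RuleResult
    in_vitro: RuleResult
    rbfox2: RuleResult
    rbfox2_labels: dict[str, str] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {rule: len(getattr(self, rule).retained) for rule in RULES}


RecordIndex = Mapping[tuple[str, str], ComparisonRecord]


def index_records(records: Iterable[ComparisonRecord]) -> dict[tuple[str, str], ComparisonRecord]:
    idx: dict[tuple[str, str], ComparisonRecord] = {}
    for r in records:
        key = (r.event_id, r.comparison_id)
        if key in idx:
            raise ValidationError(f"duplicate record for event {r.event_id!r} in {r.comparison_id!r}")
        idx[key] = r
    return idx


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify_direction(delta_psi: float) -> str:
    """Classify a flow-induced change as 'increased' or 'decreased' inclusion."""
    if delta_psi == 0:
        raise ValidationError("cannot classify direction of a zero delta-Psi")
    return "increased" if delta_psi > 0 else "decreased"


def recapitulation_fraction(delta_ref: float, delta_test: float) -> float:
    """Signed fraction of a reference splicing change reproduced in a test comparison."""
    if delta_ref == 0:
        raise ValidationError("recapitulation fraction undefined for zero reference delta-Psi")
    return delta_test / delta_ref


def reversion_fraction(delta_flow: float, delta_depleted: float) -> float:
    """Fraction of a flow-induced change reverted under depletion (1 means fully reverted)."""
    if delta_flow == 0:
        raise ValidationError("reversion fraction undefined for zero flow delta-Psi")
    return 1.0 - delta_depleted / delta_flow


def flow_regulated(
    idx: RecordIndex,
    event_ids: Sequence[str],
    flow_1: str,
    flow_2: str,
    replicate_control: str,
    cfg: SelectionConfig,
) -> RuleResult:
    """Rule 1: significant, consistent, above-replicate-noise flow regulation.

    Retains an event iff BF > threshold in both flow comparisons, the two
    delta-Psi share a sign, and the smaller |delta-Psi| exceeds
    ``replicate_ratio`` times the replicate-control |delta-Psi| (the minimum
    of the two is the conservative choice of which comparison the ratio
    applies to).
    """
    retained: set[str] = set()
    rows = []
    for ev in event_ids:
        r1 = idx.get((ev, flow_1))
        r2 = idx.get((ev, flow_2))
        rc = idx.get((ev, replicate_control))
        row = {"event_id": ev, "rule": "flow", "passed": False, "reason": ""}
        if r1 is None or r2 is None or rc is None:
            row["reason"] = "incomplete"
            rows.append(row)
            continue
        row.update(
            bf_1=r1.bayes_factor,
            bf_2=r2.bayes_factor,
            dpsi_1=r1.delta_psi,
            dpsi_2=r2.delta_psi,
            dpsi_control=rc.delta_psi,
        )
        if not (r1.bayes_factor > cfg.bf_threshold and r2.bayes_factor > cfg.bf_threshold):
            row["reason"] = "bayes_factor"
        elif _sign(r1.delta_psi) != _sign(r2.delta_psi) or r1.delta_psi == 0:
            row["reason"] = "sign"
        elif not min(abs(r1.delta_psi), abs(r2.delta_psi)) > cfg.replicate_ratio * abs(rc.delta_psi):
            row["reason"] = "replicate_ratio"
        else:
            row["passed"] = True
            row["reason"] = "pass"
            retained.add(ev)
        rows.append(row)
    return RuleResult("flow", retained, pd.DataFrame(rows))


def _mean_flow_delta(idx: RecordIndex, ev: str, flow_1: str, flow_2: str) -> float | None:
    r1 = idx.get((ev, flow_1))
    r2 = idx.get((ev, flow_2))
    if r1 is None or r2 is None:
        return None
    return 0.5 * (r1.delta_psi + r2.delta_psi)


def recapitulation_rule(
    idx: RecordIndex,
    prior: Iterable[str],
    flow_1: str,
    flow_2: str,
    test_comparison: str,
    cfg: SelectionConfig,
    rule: str,
    inclusive: bool,
) -> RuleResult:
    """Shared machinery of the endothelial (inclusive) and in-vitro (strict) rules.

    The reference change is the mean flow delta-Psi over the two independent
    flow comparisons.
    """
    retained: set[str] = set()
    rows = []
    for ev in sorted(prior):
        row = {"event_id": ev, "rule": rule, "passed": False, "reason": ""}
        ref = _mean_flow_delta(idx, ev, flow_1, flow_2)
        rt = idx.get((ev, test_comparison))
        if ref is None or rt is None:
            row["reason"] = "incomplete"
        elif ref == 0:
            row["reason"] = "undefined_reference"
        else:
            frac = recapitulation_fraction(ref, rt.delta_psi)
            row["recapitulation"] = frac
            ok = frac >= cfg.recapitulation_min if inclusive else frac > cfg.recapitulation_min
            if ok:
                row["passed"] = True
                row["reason"] = "pass"
                retained.add(ev)
            else:
                row["reason"] = "recapitulation"
        rows.append(row)
    return RuleResult(rule, retained, pd.DataFrame(rows))


def platelet_regulated(
    idx: RecordIndex,
    prior: Iterable[str],
    igg_depl_pairs: Sequence[tuple[str, str]],
    cfg: SelectionConfig,
) -> RuleResult:
    """Rule 3: platelet depletion reverts the flow change by more than
    ``reversion_min`` in every (IgG-control, depleted) comparison pair."""
    retained: set[str] = set()
    rows = []
    for ev in sorted(prior):
        row = {"event_id": ev, "rule": "platelet", "passed": False, "reason": ""}
        fracs = []
        reason = ""
        for i, (igg, depl) in enumerate(igg_depl_pairs, start=1):
            ri = idx.get((ev, igg))
            rd = idx.get((ev, depl))
            if ri is None or rd is None:
                reason = "incomplete"
                break
            if ri.delta_psi == 0:
                reason = "undefined_reference"
                break
            frac = reversion_fraction(ri.delta_psi, rd.delta_psi)
            row[f"reversion_{i}"] = frac
            fracs.append(frac)
        if reason:
            row["reason"] = reason
        elif all(f > cfg.reversion_min for f in fracs):
            row["passed"] = True
            row["reason"] = "pass"
            retained.add(ev)
        else:
            row["reason"] = "reversion"
        rows.append(row)
    return RuleResult("platelet", retained, pd.DataFrame(rows))


def rbfox2_regulated(
    idx: RecordIndex,
    candidates: Iterable[str],
    bf_comparisons: Sequence[str],
    invivo_low_comparisons: Sequence[str],
    flow_1: str,
    flow_2: str,
    cfg: SelectionConfig,
) -> tuple[RuleResult, dict[str, str]]:
    """Rule 5: Rbfox2-dependent events among the flow-regulated set.

    Retains an event iff BF > threshold in at least one of the knockout
    comparisons and all in vivo low-flow knockout-vs-control delta-Psi share
    one sign.  The label is "reverted" when that sign opposes the
    flow-induced direction, else "same".
    """
    retained: set[str] = set()
    labels: dict[str, str] = {}
    rows = []
    for ev in sorted(candidates):
        row = {"event_id": ev, "rule": "rbfox2", "passed": False, "reason": ""}
        bf_recs = [idx.get((ev, c)) for c in bf_comparisons]
        low_recs = [idx.get((ev, c)) for c in invivo_low_comparisons]
        flow_ref = _mean_flow_delta(idx, ev, flow_1, flow_2)
        if any(r is None for r in bf_recs + low_recs) or flow_ref is None:
            row["reason"] = "incomplete"
            rows.append(row)
            continue
        row["bf_max"] = max(r.bayes_factor for r in bf_recs)
        if not any(r.bayes_factor > cfg.bf_threshold for r in bf_recs):
            row["reason"] = "bayes_factor"
            rows.append(row)
            continue
        signs = {_sign(r.delta_psi) for r in low_recs}
        if len(signs) != 1 or 0 in signs:
            row["reason"] = "inconsistent_direction" if 0 not in signs else "zero_delta"
            rows.append(row)
            continue
        ko_sign = signs.pop()
        if flow_ref == 0:
            row["reason"] = "undefined_reference"
            rows.append(row)
            continue
        label = "reverted" if ko_sign != _sign(flow_ref) else "same"
        row["passed"] = True
        row["reason"] = "pass"
        row["label"] = label
        retained.add(ev)
        labels[ev] = label
        rows.append(row)
    return RuleResult("rbfox2", retained, pd.DataFrame(rows)), labels


def run_cascade(
    records: Iterable[ComparisonRecord],
    roles: Mapping[str, str],
    cfg: SelectionConfig | None = None,
    event_ids: Sequence[str] | None = None,
) -> SelectionReport:
    """Run all five rules; later tiers only see events retained by earlier ones.

    ``roles`` maps each name in :data:`ROLE_NAMES` to a comparison_id present
    in ``records``.
    """
    cfg = cfg or SelectionConfig()
    missing = [r for r in ROLE_NAMES if r not in roles]
    if missing:
        raise ValidationError(f"missing comparison roles: {missing}")
    idx = index_records(records) if not isinstance(records, dict) else records
    if event_ids is None:
        seen: list[str] = []
        seen_set: set[str] = set()
        for ev, _ in idx:
            if ev not in seen_set:
                seen.append(ev)
                seen_set.add(ev)
        event_ids = seen

    flow = flow_regulated(idx, event_ids, roles["flow_1"], roles["flow_2"], roles["replicate_control"], cfg)
    endo = recapitulation_rule(
        idx, flow.retained, roles["flow_1"], roles["flow_2"], roles["endothelial"], cfg,
        rule="endothelial", inclusive=True,
    )
    platelet = platelet_regulated(
        idx,
        endo.retained,
        [
            (roles["platelet_igg_1"], roles["platelet_depl_1"]),
            (roles["platelet_igg_2"], roles["platelet_depl_2"]),
        ],
        cfg,
    )
    in_vitro = recapitulation_rule(
        idx, platelet.retained, roles["flow_1"], roles["flow_2"], roles["in_vitro"], cfg,
        rule="in_vitro", inclusive=False,
    )
    rbfox2, labels = rbfox2_regulated(
        idx,
        flow.retained,
        [roles["rbfox2_invivo_low_1"], roles["rbfox2_invivo_high"], roles["rbfox2_invitro"]],
        [roles["rbfox2_invivo_low_1"], roles["rbfox2_invivo_low_2"]],
        roles["flow_1"],
        roles["flow_2"],
        cfg,
    )

    directions = {}
    for ev in flow.retained:
        ref = _mean_flow_delta(idx, ev, roles["flow_1"], roles["flow_2"])
        if ref:
            directions[ev] = classify_direction(ref)
    return SelectionReport(
        flow=flow,
        endothelial=endo,
        platelet=platelet,
        in_vitro=in_vitro,
        rbfox2=rbfox2,
        rbfox2_labels=labels,
        directions=directions,
    )
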
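"""Transport-pattern classification and condition-specific call sets.

The one-grafted-plant / three-samples design distinguishes three downward
transport classes by set membership of a gene's receiving tissues:

* ``rl_direct`` — detected in the lateral-branch leaf (RL) but not the
  root (RR): moved to the distal leaf without passing through root tissue;
* ``rr_only`` — detected in RR but not RL: degraded (or diluted below
  detection) in transit before reaching the leaf;
* ``through_root`` — detected in both: moved scion (HL) -> root (RR) ->
  leaf (RL).

These are set-theoretic labels, not a kinetic model. Condition-specific
sets are the exact three-way Venn partition of CK vs drought calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .caller import MobileCall
from .io import ValidationError


@dataclass
class TransportPatternSummary:
    """Three-way partition of downward mobile genes plus totals."""

    rr_set: frozenset[str]
    rl_set: frozenset[str]
    total_up: int = 0
    condition: str | None = None

    # derived, filled in __post_init__
    through_root: frozenset[str] = field(init=False)
    rl_direct: frozenset[str] = field(init=False)
    rr_only_degraded: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.through_root = frozenset(self.rr_set & self.rl_set)
        self.rl_direct = frozenset(self.rl_set - self.rr_set)
        self.rr_only_degraded = frozenset(self.rr_set - self.rl_set)

    @property
    def total_down(self) -> int:
        return len(self.rr_set | self.rl_set)

    def counts(self) -> dict[str, int]:
        return {
            "total_down": self.total_down,
            "rr": len(self.rr_set),
            "rl": len(self.rl_set),
            "through_root": len(self.through_root),
            "rl_direct": len(self.rl_direct),
            "rr_only_degraded": len(self.rr_only_degraded),
            "total_up": self.total_up,
        }

    def check(self) -> None:
        """Inclusion-exclusion identities the partition must satisfy."""
        assert self.total_down == len(self.rr_set) + len(self.rl_set) - len(
            self.through_root
        )
        assert len(self.rl_direct) == len(self.rl_set) - len(self.through_root)
        assert len(self.rr_only_degraded) == len(self.rr_set) - len(self.through_root)
        union = self.through_root | self.rl_direct | self.rr_only_degraded
        assert union == (self.rr_set | self.rl_set)
        assert not (self.through_root & self.rl_direct)
        assert not (self.through_root & self.rr_only_degraded)
        assert not (self.rl_direct & self.rr_only_degraded)


def classify_transport(
    calls: Iterable[MobileCall],
    condition: str | None = None,
) -> TransportPatternSummary:
    """Partition downward mobile genes by receiving-tissue membership.

    *calls* may come from one condition or a merged set; pass *condition*
    to label the summary (``None`` flags a merged/pooled set). A downward
    call in tissue HL is a contract violation and raises.
    """
    rr: set[str] = set()
    rl: set[str] = set()
    up: set[str] = set()
    for c in calls:
        if c.direction == "down":
            if c.tissue == "RR":
                rr.add(c.gene_id)
            elif c.tissue == "RL":
                rl.add(c.gene_id)
            else:
                raise ValidationError(
                    f"downward call {c.gene_id} in non-rootstock tissue {c.tissue}"
                )
        elif c.direction == "up":
            if c.tissue != "HL":
                raise ValidationError(
                    f"upward call {c.gene_id} in non-scion tissue {c.tissue}"
                )
            up.add(c.gene_id)
        else:
            raise ValidationError(f"unknown direction {c.direction!r}")
    summary = TransportPatternSummary(
        rr_set=frozenset(rr),
        rl_set=frozenset(rl),
        total_up=len(up),
        condition=condition,
    )
    summary.check()
    return summary


def transport_from_sets(
    rr_set: Iterable[str],
    rl_set: Iterable[str],
    total_up: int = 0,
    condition: str | None = None,
) -> TransportPatternSummary:
    """Build the summary directly from receiving-tissue gene sets."""
    summary = TransportPatternSummary(
        rr_set=frozenset(rr_set),
        rl_set=frozenset(rl_set),
        total_up=total_up,
        condition=condition,
    )
    summary.check()
    return summary


@dataclass
class ConditionVenn:
    """Three-way partition of calls in one tissue x direction: CK-only,
    shared, drought-only."""

    tissue: str
    direction: str
    ck_only: frozenset[str]
    both: frozenset[str]
    drought_only: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "ck_only": len(self.ck_only),
            "both": len(self.both),
            "drought_only": len(self.drought_only),
        }


def _homogeneous(calls: Sequence[MobileCall], label: str) -> tuple[str, str] | None:
    keys = {(c.tissue, c.direction) for c in calls}
    if len(keys) > 1:
        raise ValidationError(f"{label} call list mixes tissues/directions: {sorted(keys)}")
    return next(iter(keys)) if keys else None


def condition_specific_sets(
    calls_ck: Sequence[MobileCall],
    calls_drought: Sequence[MobileCall],
) -> ConditionVenn:
    """Exact CK/drought Venn partition for one tissue x direction.

    Symmetric in its arguments: swapping the inputs swaps the CK-only and
    drought-only cells. Mixing tissues within or across the two lists is an
    error.
    """
    key_ck = _homogeneous(calls_ck, "CK")
    key_dr = _homogeneous(calls_drought, "drought")
    if key_ck and key_dr and key_ck != key_dr:
        raise ValidationError(
            f"CK calls are {key_ck} but drought calls are {key_dr}"
        )
    key = key_ck or key_dr
    if key is None:
        raise ValidationError("cannot infer tissue/direction from two empty call lists")
    tissue, direction = key
    ck = {c.gene_id for c in calls_ck}
    dr = {c.gene_id for c in calls_drought}
    return ConditionVenn(
        tissue=tissue,
        direction=direction,
        ck_only=frozenset(ck - dr),
        both=frozenset(ck & dr),
        drought_only=frozenset(dr - ck),
    )
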
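"""Constants describing the 12-condition, 23-sample study design.

Five FACS-sorted tissues are profiled across three developmental
timepoints.  At the 20-somite stage (20SS) the two skin layers are not
separately sortable, so only ``all_skin`` and ``nonskin1`` exist there;
``periderm``, ``basal`` and ``nonskin2`` appear at 52 and 72 hpf.  Every
condition carries two biological replicates except ``nonskin2`` at
52 hpf, which has one, for 23 samples total.
"""

from __future__ import annotations

import itertools
import math

TISSUES = ("all_skin", "nonskin1", "periderm", "basal", "nonskin2")
TIMEPOINTS = ("20SS", "52hpf", "72hpf")
LATER_TIMEPOINTS = ("52hpf", "72hpf")

#: the 12 valid (tissue, timepoint) pairs
CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    [("all_skin", tp) for tp in TIMEPOINTS]
    + [("nonskin1", tp) for tp in TIMEPOINTS]
    + [(t, tp) for t in ("periderm", "basal", "nonskin2") for tp in LATER_TIMEPOINTS]
)

#: replicates per condition: two everywhere but nonskin2 @ 52 hpf
REPLICATES: dict[tuple[str, str], int] = {
    c: (1 if c == ("nonskin2", "52hpf") else 2) for c in CONDITIONS
}

N_SAMPLES = sum(REPLICATES.values())  # 23

#: log2 fold-change threshold ("1.5x")
THETA = math.log2(1.5)
#: negligibility probability for category calls
EPSILON = 0.02

#: per-timepoint category alphabets
CATEGORIES_20SS = ("S", "N")
CATEGORIES_LATER = ("N", "G", "B", "P")

#: all 32 possible flows (category combinations across the timepoints)
ALL_FLOWS: tuple[str, ...] = tuple(
    a + b + c
    for a, b, c in itertools.product(
        CATEGORIES_20SS, CATEGORIES_LATER, CATEGORIES_LATER
    )
)


def cond_label(tissue: str, timepoint: str) -> str:
    """Canonical string label for a condition, e.g. ``'periderm:52hpf'``."""
    if (tissue, timepoint) not in CONDITIONS:
        raise ValueError(f"invalid condition ({tissue}, {timepoint})")
    return f"{tissue}:{timepoint}"


def parse_cond_label(label: str) -> tuple[str, str]:
    tissue, _, timepoint = label.partition(":")
    if (tissue, timepoint) not in CONDITIONS:
        raise ValueError(f"invalid condition label {label!r}")
    return tissue, timepoint


COND_LABELS = tuple(cond_label(*c) for c in CONDITIONS)


def sample_id(tissue: str, timepoint: str, replicate: int) -> str:
    return f"{tissue}_{timepoint}_r{replicate}"


def is_valid_flow(flow: str) -> bool:
    return flow in ALL_FLOWS
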
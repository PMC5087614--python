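"""Three-control comparison design and robust target-set intersection.

Each overexpressed construct's GFP+ wells are compared against three control
sets — (1) GFP+ wells of the fluorescent-control transfection, (2) GFP- wells
of the construct and the fluorescent control, (3) all GFP- wells of the
library — and a TFE is accepted as a target only if it passes the q threshold
in all three comparisons (by default with the same direction in all three).
Gene-level target sets keep a gene if any of its coding-5'UTR TFEs passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .containers import SampleSheet, SpikeTagMatrix, DesignError, GFP_POSITIVE, GFP_NEGATIVE
from .de import DEResult, de_test
from .tfe import TFERecord, CATEGORIES
from .utils import child_seed

COMPARISON_NAMES = ("vs_control_positive", "vs_negatives_paired", "vs_negatives_library")


@dataclass
class ComparisonSpec:
    name: str
    test_samples: list[str]
    control_samples: list[str]

    def __post_init__(self) -> None:
        if self.name not in COMPARISON_NAMES:
            raise DesignError(f"unknown comparison name {self.name!r}")
        if set(self.test_samples) & set(self.control_samples):
            raise DesignError(f"{self.name}: test and control samples overlap")
        if not self.test_samples or not self.control_samples:
            raise DesignError(f"{self.name}: empty test or control set")


@dataclass
class TargetSet:
    construct: str
    up: set[str]  # gene ids
    down: set[str]
    up_tfes: set[str] = field(default_factory=set)
    down_tfes: set[str] = field(default_factory=set)
    comparisons: dict[str, DEResult] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down")


def build_comparisons(sheet: SampleSheet, construct: str) -> list[ComparisonSpec]:
    """The three control designs for one construct's GFP+ wells."""
    test = sheet.select(construct=construct, gfp=GFP_POSITIVE)
    if not test:
        raise DesignError(f"no GFP-positive wells for construct {construct!r}")
    ctrl = sheet.fluorescent_control
    ctrl_pos = sheet.select(construct=ctrl, gfp=GFP_POSITIVE)
    if not ctrl_pos:
        raise DesignError(f"no GFP-positive wells for fluorescent control {ctrl!r}")
    paired_neg = sorted(
        set(sheet.select(construct=construct, gfp=GFP_NEGATIVE))
        | set(sheet.select(construct=ctrl, gfp=GFP_NEGATIVE))
    )
    library_neg = sheet.select(gfp=GFP_NEGATIVE)
    return [
        ComparisonSpec("vs_control_positive", test, ctrl_pos),
        ComparisonSpec("vs_negatives_paired", test, paired_neg),
        ComparisonSpec("vs_negatives_library", test, library_neg),
    ]


def run_comparisons(
    matrix: SpikeTagMatrix,
    sheet: SampleSheet,
    construct: str,
    D: int = 20,
    B: int = 100,
    seed: int = 0,
) -> dict[str, DEResult]:
    """Run the DE test for all three comparison designs of one construct."""
    out = {}
    for spec in build_comparisons(sheet, construct):
        out[spec.name] = de_test(
            matrix,
            spec.test_samples,
            spec.control_samples,
            D=D,
            B=B,
            seed=child_seed(seed, construct, spec.name),
        )
    return out


def intersect_calls(
    comparisons: dict[str, DEResult],
    tfes: Optional[Iterable[TFERecord]] = None,
    q_threshold: float = 0.1,
    construct: str = "",
    require_direction_concordance: bool = True,
    gene_categories: Iterable[str] = ("utr5_coding",),
) -> TargetSet:
    """Intersect three per-comparison call tables into a robust target set.

    A TFE is a target iff q < ``q_threshold`` in every comparison, and (by
    default) with the same direction everywhere — a feature flipping sign
    between control sets is not a coherent target.  When annotated ``tfes``
    are given, TFE-level calls are reduced to gene ids via the categories in
    ``gene_categories``; otherwise gene sets echo the TFE ids.
    """
    if len(comparisons) != 3:
        raise ValueError("expected exactly three comparison tables")
    tables = list(comparisons.values())
    universe = set(tables[0].table.index)
    for t in tables[1:]:
        if set(t.table.index) != universe:
            raise ValueError("comparison tables cover different TFE universes")

    up_tfes, down_tfes = set(), set()
    sig = [t.table[t.table["q"] < q_threshold] for t in tables]
    common = set(sig[0].index)
    for s in sig[1:]:
        common &= set(s.index)
    for tfe_id in common:
        dirs = {t.table.loc[tfe_id, "direction"] for t in tables}
        if require_direction_concordance:
            if len(dirs) > 1:
                continue
            (d,) = dirs
        else:
            # majority direction of the per-comparison statistics
            stats = sum(t.table.loc[tfe_id, "statistic"] for t in tables)
            d = "down" if stats < 0 else "up"
        (up_tfes if d == "up" else down_tfes).add(tfe_id)

    if tfes is not None:
        by_id = {t.id: t for t in tfes}
        keep = set(gene_categories)

        def genes(ids: set[str]) -> set[str]:
            out = set()
            for i in ids:
                rec = by_id.get(i)
                if rec is not None and rec.category in keep and rec.gene_id:
                    out.add(rec.gene_id)
            return out

        up, down = genes(up_tfes), genes(down_tfes)
        down -= up  # a gene with discordant TFEs counts once, as activated
    else:
        up, down = set(up_tfes), set(down_tfes)
    return TargetSet(
        construct=construct,
        up=up,
        down=down,
        up_tfes=up_tfes,
        down_tfes=down_tfes,
        comparisons=dict(comparisons),
    )


def summarize_regions(targets: TargetSet, tfes: Iterable[TFERecord]) -> pd.DataFrame:
    """Counts of up/down target TFEs per genomic category (Fig-3D-style table)."""
    by_id = {t.id: t for t in tfes}
    table = pd.DataFrame(0, index=list(CATEGORIES), columns=["up", "down"])
    for ids, col in ((targets.up_tfes, "up"), (targets.down_tfes, "down")):
        for i in ids:
            rec = by_id.get(i)
            if rec is None or rec.category is None:
                raise ValueError(f"target TFE {i} missing annotation")
            table.loc[rec.category, col] += 1
    table.index.name = "category"
    return table
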
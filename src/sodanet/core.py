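"""Core-microbiome partitioning across lakes.

An OTU belongs to the *core* of a lake set if it is detected (at least one
read, pooled over the whole study period, after rarefaction) in every lake of
the set — the "core5"/"core4" style of definition.  Each lake's non-core set
is whatever it detected that is not core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OtuTable


@dataclass
class CorePartition:
    lakes_considered: tuple
    core: set
    noncore: dict  # lake -> set of OTU ids detected in that lake but not core
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = f"core{len(self.lakes_considered)}"

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: otu_id, label in {core, noncore:<lake>}."""
        rows = [{"otu_id": o, "label": self.label} for o in sorted(self.core)]
        for lake in self.lakes_considered:
            rows.extend(
                {"otu_id": o, "label": f"noncore:{lake}"}
                for o in sorted(self.noncore[lake])
            )
        return pd.DataFrame(rows, columns=["otu_id", "label"])


def detected_otus(table: OtuTable) -> set:
    """OTUs with total count > 0 pooled over the lake's samples."""
    totals = table.data.sum(axis=0)
    return set(totals.index[totals > 0])


def partition_core(tables: dict, lakes=None, label: str = "") -> CorePartition:
    """Partition OTUs into core (present in every listed lake) and non-core.

    ``tables`` maps lake name to its (rarefied) count table; ``lakes``
    selects the subset considered (default: all).
    """
    lakes = tuple(lakes) if lakes is not None else tuple(tables)
    if len(lakes) < 2:
        raise ValueError("core partition needs at least two lakes")
    unknown = [lk for lk in lakes if lk not in tables]
    if unknown:
        raise ValueError(f"unknown lake name(s): {unknown}")
    detected = {lk: detected_otus(tables[lk]) for lk in lakes}
    core = set.intersection(*detected.values())
    noncore = {lk: detected[lk] - core for lk in lakes}
    return CorePartition(lakes_considered=lakes, core=core, noncore=noncore, label=label)


def core_contribution(table: OtuTable, core: set):
    """Share of reads belonging to the core, per sample and pooled.

    Core ids absent from the table contribute zero.  Returns
    ``(per_sample, pooled)`` where ``per_sample`` is a Series of fractions in
    [0, 1] indexed by sample id and ``pooled`` is the study-wide read share.
    """
    totals = table.data.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero reads")
    present_core = [o for o in table.otu_ids if o in core]
    core_reads = (
        table.data[present_core].sum(axis=1)
        if present_core
        else pd.Series(0.0, index=table.data.index)
    )
    per_sample = core_reads / totals
    pooled = float(core_reads.sum() / totals.sum())
    return per_sample, pooled
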
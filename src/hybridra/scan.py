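"""Knock-out / knock-in scan over regulatory initial conditions.

Every component of the base condition is flipped in turn (1 -> 0 is a
knock-out, 0 -> 1 a knock-in) while all others keep their base values; the
full pipeline — propagation, trap spaces, projection, constraint
extraction, FBA — is re-run per variant and the ATP-source split
collected.  The unflipped base condition is included as a reference row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .bridge import MetabolicMapping
from .errors import ValidationError
from .metab_io import MetabolicModel, ObjectiveSpec
from .pipeline import analyze_condition
from .qual_io import BooleanNetwork, Condition

logger = logging.getLogger("hybridra.scan")

__all__ = ["ScanTable", "koki_scan"]


@dataclass
class ScanTable:
    """One row per scanned variant plus the base reference row."""

    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=[
            "variant", "component", "flipped_to", "glycolysis_pct",
            "oxphos_pct", "n_constraints", "status"])

    def render(self) -> str:
        """Plain-text table: components x variants with the flipped value,
        plus the ATP-source split per variant."""
        df = self.to_frame()
        lines = [df.to_string(index=False, float_format=lambda x: f"{x:.1f}")]
        return "\n".join(lines)

    def row_for(self, component: str) -> dict:
        for row in self.rows:
            if row["component"] == component:
                return row
        raise KeyError(component)


def koki_scan(net: BooleanNetwork, base: Condition, model: MetabolicModel,
              mapping: MetabolicMapping, objective: ObjectiveSpec,
              glycolytic_terms, oxphos_terms, scan_set=None,
              parsimonious: bool = False, unclamp: bool = False,
              trapspace_budget: int = 500_000) -> ScanTable:
    """Single-component flip scan with full pipeline re-execution.

    ``scan_set`` restricts which components of ``base`` are flipped
    (default: all of them); an infeasible variant keeps its row with
    status ``infeasible`` and blank fractions.
    """
    base.resolve(net)
    if scan_set is None:
        scan_set = list(base.assignments)
    else:
        scan_set = list(scan_set)
        missing = [c for c in scan_set if c not in base.assignments]
        if missing:
            raise ValidationError(
                f"scan components not in base condition: {missing}")

    def run(cond: Condition, variant: str, component: str, flipped_to):
        res = analyze_condition(net, cond, model, mapping, objective,
                                glycolytic_terms, oxphos_terms,
                                parsimonious=parsimonious, unclamp=unclamp,
                                trapspace_budget=trapspace_budget)
        row = {
            "variant": variant,
            "component": component,
            "flipped_to": flipped_to,
            "glycolysis_pct": res.atp.glycolysis_pct if res.atp else None,
            "oxphos_pct": res.atp.oxphos_pct if res.atp else None,
            "n_constraints": len(res.constraints),
            "status": res.solution.status,
        }
        return row

    table = ScanTable()
    table.rows.append(run(base, "base", "", None))
    for i, comp in enumerate(c for c in base.assignments if c in set(scan_set)):
        cond = base.flip(comp)
        flipped_to = cond.assignments[comp]
        logger.info("scan variant C%d: %s -> %d", i + 1, comp, flipped_to)
        table.rows.append(run(cond, f"C{i + 1}", comp, flipped_to))
    return table
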
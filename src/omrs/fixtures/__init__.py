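"""Packaged data fixtures."""

from __future__ import annotations

import json
from importlib import resources

from ..cohort_stats import ContingencyTable2x2


def load_table2_counts() -> dict:
    """The shipped 2x2 progression tables of the prognostic cohort."""
    with resources.files(__package__).joinpath("table2_counts.json").open() as fh:
        return json.load(fh)


def contingency_table(name: str) -> ContingencyTable2x2:
    """One shipped table as a :class:`ContingencyTable2x2` (e.g. "omrs_risk")."""
    t = load_table2_counts()["tables"][name]
    return ContingencyTable2x2(t["a"], t["b"], t["c"], t["d"])
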
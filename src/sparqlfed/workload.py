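"""The 20-query federated benchmark workload: published per-query statistics.

Ten simple (SQ1–SQ10) and ten complex (CQ1–CQ10) federated queries over the
ten-dataset life-science federation, characterized by BGP count, triple
pattern count, total vertices, join vertices, join ratio R and mean join
degree D, plus the SPARQL clauses used.  The verbatim query texts are not part
of this package; the statistics table is treated as input data, chiefly to
reproduce the index-free source-selection baseline: an engine with no
catalogue must ASK every dataset about every triple pattern, so its cold ASK
budget is (number of datasets) x (total triple patterns) — 10 x 139 = 1390
for this workload.

Note the SQ9 row is reproduced exactly as published even though its R value is
inconsistent with its printed vertex count (2/14 is 0.142, not 0.117).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

__all__ = ["WorkloadQueryStats", "BENCHMARK_WORKLOAD", "workload_tp_total", "index_free_baseline_total"]


@dataclass(frozen=True)
class WorkloadQueryStats:
    name: str
    complexity: str  # "simple" | "complex"
    bgp_count: int
    tp_count: int
    total_vertices: int
    join_vertices: int
    ratio: float  # as printed (truncated to 3 decimals)
    mean_join_degree: float
    clauses: Tuple[str, ...]


BENCHMARK_WORKLOAD: Tuple[WorkloadQueryStats, ...] = (
    WorkloadQueryStats("SQ1", "simple", 2, 4, 10, 2, 0.20, 2.0, ("UNION",)),
    WorkloadQueryStats("SQ2", "simple", 1, 7, 15, 4, 0.266, 2.5, ()),
    WorkloadQueryStats("SQ3", "simple", 1, 6, 13, 4, 0.307, 2.250, ()),
    WorkloadQueryStats("SQ4", "simple", 1, 5, 11, 3, 0.272, 2.333, ()),
    WorkloadQueryStats("SQ5", "simple", 2, 5, 12, 3, 0.250, 2.0, ("OPTIONAL",)),
    WorkloadQueryStats("SQ6", "simple", 1, 3, 7, 2, 0.285, 2.0, ()),
    WorkloadQueryStats("SQ7", "simple", 1, 4, 9, 3, 0.333, 2.0, ()),
    WorkloadQueryStats("SQ8", "simple", 1, 3, 7, 2, 0.285, 2.0, ()),
    WorkloadQueryStats("SQ9", "simple", 1, 8, 14, 2, 0.117, 4.5, ("DISTINCT",)),
    WorkloadQueryStats("SQ10", "simple", 1, 8, 17, 2, 0.117, 4.5, ("DISTINCT",)),
    WorkloadQueryStats("CQ1", "complex", 2, 8, 18, 4, 0.222, 2.5, ("DISTINCT", "OPTIONAL", "FILTER")),
    WorkloadQueryStats("CQ2", "complex", 2, 8, 19, 4, 0.210, 2.25, ("OPTIONAL", "FILTER")),
    WorkloadQueryStats("CQ3", "complex", 1, 10, 19, 4, 0.210, 3.75, ("DISTINCT", "FILTER", "REGEX")),
    WorkloadQueryStats("CQ4", "complex", 1, 6, 13, 4, 0.307, 2.25, ()),
    WorkloadQueryStats("CQ5", "complex", 2, 10, 22, 3, 0.136, 3.666, ("OPTIONAL",)),
    WorkloadQueryStats("CQ6", "complex", 2, 12, 24, 6, 0.25, 3.0, ("OPTIONAL",)),
    WorkloadQueryStats("CQ7", "complex", 1, 8, 17, 4, 0.235, 2.75, ()),
    WorkloadQueryStats("CQ8", "complex", 1, 6, 13, 2, 0.153, 3.5, ()),
    WorkloadQueryStats("CQ9", "complex", 1, 9, 19, 5, 0.263, 2.6, ("FILTER",)),
    WorkloadQueryStats("CQ10", "complex", 2, 9, 20, 3, 0.15, 3.333, ("OPTIONAL",)),
)


def workload_tp_total() -> int:
    """Total triple patterns across the 20-query workload (139)."""
    return sum(q.tp_count for q in BENCHMARK_WORKLOAD)


def index_free_baseline_total(n_datasets: int = 10) -> int:
    """Cold index-free ASK budget for the whole workload: datasets x patterns."""
    return n_datasets * workload_tp_total()
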
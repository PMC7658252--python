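"""synforge: forward-synthesis virtual library generation.

Expert-system reaction rules (role SMARTS + product SMIRKS + ADD/SUBTRACT/KILL
scoring clauses) applied to a prepared building-block pool produce scored,
classified, deprotected, annotated virtual products, together with
library-level bookkeeping: class distributions, success rates, combinatorial
estimates, ring-system census and database overlap.
"""

from importlib import resources

from .analysis import (
    class_distribution,
    class_distribution_from_counts,
    kill_loss_rate,
    load_reference_run,
    overlap,
    ring_system_census,
    ring_systems,
    round_sig,
    sar_neighbors,
    success_ratio,
    theoretical_max,
)
from .annotate import (
    ProductAnnotation,
    annotate,
    demerit_score,
    pains_count,
    qed_score,
    ro3_violations,
    ro5_violations,
)
from .bbs import (
    BuildingBlock,
    FilterConfig,
    RoleSet,
    assign_roles,
    deduplicate,
    filter_bb,
    prepare,
    standardize,
)
from .deprotect import deprotect, detect_pgs, suffix_id
from .engine import (
    EngineConfig,
    LibraryRunResult,
    ReactionRecord,
    apply_transform,
    classify_score,
    enumerate_pairs,
    run_library,
    score_reaction,
)
from .fixtures import DEFAULT_SPEC, LibrarySpec, generate_library, write_library
from .rules import Transform, ScoringClause, load_rules, serialize_rules, validate_transform

__version__ = "0.1.0"


def builtin_rules():
    """Load the shipped standard rule set."""
    ref = resources.files("synforge.data") / "rules/standard_rules.yaml"
    with resources.as_file(ref) as path:
        return load_rules(str(path))
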
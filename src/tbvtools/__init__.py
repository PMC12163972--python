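"""tbvtools: total blood volume estimation and apheresis procedure planning
for obese patients.

The package evaluates the common clinical TBV estimators (Nadler,
Lemmens-Bernstein, Gilcher's rule of fives) on actual or adjusted ideal body
weight, derives apheresis procedure parameters (red cell / plasma exchange
unit counts, multi-volume collection times) from the estimates, and compares
the formulas across an obese cohort: difference curves against a 500 mL
functional-significance threshold, expected-range coverage, and severity-
class mean comparisons.  A seeded synthetic cohort generator provides test
cohorts with the assumed structure.
"""

__version__ = "0.1.0"

from .anthropometry import (  # noqa: E402,F401
    AnthropometricProfile,
    ObesityClass,
    PatientRecord,
    Sex,
    adjusted_ibw,
    classify_obesity,
    compute_bmi,
    devine_ibw,
    profile_for,
)
from .config import RunConfig, load_config  # noqa: F401
from .comparison import (  # noqa: F401
    DifferencePoint,
    GroupComparison,
    RangeCoverage,
    compare_severity_groups,
    difference_curve,
    range_coverage,
    summarize_formula,
)
from .errors import (  # noqa: F401
    ConfigurationError,
    DataError,
    StatisticsError,
    TbvToolsError,
    ValidationError,
)
from .estimators import (  # noqa: F401
    EstimateSet,
    FormulaId,
    TbvEstimate,
    WeightBasis,
    estimate_all,
    gilcher,
    lemmens_bernstein,
    nadler,
)
from .pipeline import (  # noqa: F401
    AnalysisBundle,
    hypothetical_patient_tables,
    run_pipeline,
)
from .planning import (  # noqa: F401
    CollectionPlan,
    ExchangeModel,
    ExchangePlan,
    blood_compartments,
    plan_collection,
    plan_rce,
    plan_tpe,
)
from .rounding import round_half_up  # noqa: F401
from .synthetic import SyntheticCohortConfig, generate, inject_class_shift  # noqa: F401
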
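"""Published reference data from the Alberta 2008 validation study.

The study population comprised 1,118,097 adults with at least one
outpatient serum-creatinine measurement in calendar 2008; 2,227 of them
were chronic dialysis patients in the provincial ESRD registry (the
reference standard). For each of the four claims-based case definitions
the published 2x2 contingency counts against the registry are recorded
here, so the full statistics table can be recomputed without access to
the underlying (non-public) claims and registry data.
"""

from __future__ import annotations

from .agreement import TwoByTwo
from .definitions import Definition

#: Adults with >= 1 outpatient serum creatinine in 2008 (study N).
POPULATION_TOTAL = 1_118_097

#: Chronic dialysis patients in the ESRD registry during 2008.
REGISTRY_TOTAL = 2_227

#: Published 2x2 counts (a, b, c, d) per case definition.
REFERENCE_TABLES: dict[Definition, TwoByTwo] = {
    Definition.ONE_CLAIM: TwoByTwo(1805, 519, 422, 1_115_351),
    Definition.TWO_CLAIMS: TwoByTwo(1751, 420, 476, 1_115_450),
    Definition.TWO_CLAIMS_90D: TwoByTwo(1406, 251, 821, 1_115_619),
    Definition.CONTINUOUS_90D: TwoByTwo(1295, 213, 932, 1_115_657),
}
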
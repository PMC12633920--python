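"""Central institutions: secular, universal insecurity relief.

From ``ci_start_year`` on, every living agent receives a fixed yearly
reduction in insecurity, and in exchange every adult (strictly older than
``ci_min_tax_age``) pays a fixed wellbeing cost — a rough analogue of a
tax-funded welfare state that supplies security independent of religiosity.
The institution never touches religiosity directly; any religiosity change
in CI runs is mediated by how often prosocial behaviour still fires.
"""

from __future__ import annotations

import numpy as np

from .config import InstitutionParams

__all__ = ["apply_central_institution"]


def apply_central_institution(
    society, params: InstitutionParams, year: int, ci_start_year: int = 200
) -> None:
    """Apply one year of the central-institution effect in place.

    No-op before ``ci_start_year`` or when the institution is disabled.
    """
    if not params.ci_enabled or year < ci_start_year:
        return
    ins = society.insecurity
    np.maximum(ins - params.ci_benefit, 0.0, out=ins)
    taxed = society.age > params.ci_min_tax_age
    wb = society.wellbeing
    wb[taxed] = np.maximum(wb[taxed] - params.ci_wb_cost, 0.0)
    society.anxiety[:] = ins * society.sensitivity
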
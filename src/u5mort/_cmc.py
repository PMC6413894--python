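"""Century-month-code (CMC) date arithmetic.

The CMC is the DHS survey date encoding: months elapsed since January
1900, with CMC 1 = January 1900.  All age arithmetic in the package is in
completed months, so dates never need finer resolution than a CMC.
"""

from __future__ import annotations

import numpy as np


def cmc(year: int | np.ndarray, month: int | np.ndarray):
    """CMC of a calendar (year, month) with month in 1..12."""
    return 12 * (np.asarray(year) - 1900) + np.asarray(month)


def cmc_year(code):
    """Calendar year containing the month coded by ``code``."""
    return 1900 + (np.asarray(code) - 1) // 12


def cmc_month(code):
    """Calendar month (1..12) of the month coded by ``code``."""
    return (np.asarray(code) - 1) % 12 + 1
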
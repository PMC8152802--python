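"""Small built-in reference tables.

Published biweekly ovitrap totals of *Aedes japonicus* eggs for the
Reichstett study site (12 ovitraps) and the surrounding Bas-Rhin
department surveillance network, seasons 2019 and 2020.  Counts are summed
per two weeks and labelled by the first ISO week of each bin.  These
serve as worked-example inputs for the abundance operations; the grand
totals (25,809 / 16,859 / 5,551 / 8,610) are the published season totals.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reichstett_biweekly_counts", "bas_rhin_biweekly_counts"]

_REICHSTETT = {
    2019: [
        (20, 16), (22, 921), (24, 3525), (26, 3994), (28, 2466), (30, 4339),
        (32, 2338), (34, 2412), (36, 1112), (38, 791), (40, 2448), (42, 1336),
        (44, 60), (46, 51),
    ],
    2020: [
        (20, 529), (22, 1592), (24, 1243), (26, 1489), (28, 1698), (30, 3491),
        (32, 2136), (34, 1338), (36, 876), (38, 172), (40, 1992), (42, 200),
        (44, 103),
    ],
}

_BAS_RHIN = {
    2019: [
        (21, 395), (23, 395), (25, 858), (27, 247), (29, 943), (31, 833),
        (33, 1078), (35, 382), (37, 19), (39, 34), (41, 152), (43, 215),
    ],
    2020: [
        (25, 306), (27, 680), (29, 2604), (31, 1512), (33, 1073), (35, 1499),
        (37, 487), (39, 228), (41, 221), (43, 0),
    ],
}


def _frame(table: dict[int, list[tuple[int, int]]]) -> pd.DataFrame:
    rows = [
        {"iso_year": y, "iso_week": w, "count": c}
        for y, pairs in table.items()
        for w, c in pairs
    ]
    return pd.DataFrame(rows)


def reichstett_biweekly_counts() -> pd.DataFrame:
    """Biweekly egg totals at the Reichstett site, 2019-2020.

    Columns: iso_year, iso_week (first week of the two-week bin), count.
    """
    return _frame(_REICHSTETT)


def bas_rhin_biweekly_counts() -> pd.DataFrame:
    """Biweekly egg totals of the Bas-Rhin surveillance network, 2019-2020."""
    return _frame(_BAS_RHIN)
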
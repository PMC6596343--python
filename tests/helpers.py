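"""Shared test utilities: toy-table construction and a brute-force oracle."""

from __future__ import annotations

import pandas as pd

from capsip.sip_tables import AbundanceTable, LibraryKey

FILLER = "OTU_filler"


def quad_table(
    quads: list[tuple[float, float, float, float]],
    *,
    oxygen: str = "oxic",
    day: float = 3.0,
    t0: float = 0.0,
) -> AbundanceTable:
    """Percent table realizing one (R_a, R_b, R_c, R_d) quadruple per OTU.

    Columns are the four libraries the detector needs (heavy-13C at t0 and
    at ``day``, heavy-12C and light-13C at ``day``); a filler OTU absorbs
    the remainder so each column sums to 100.
    """
    otus = [f"OTU_{i + 1}" for i in range(len(quads))] + [FILLER]
    cols = {
        LibraryKey("13C", oxygen, day, "heavy"): [q[0] for q in quads],
        LibraryKey("12C", oxygen, day, "heavy"): [q[1] for q in quads],
        LibraryKey("13C", oxygen, day, "light"): [q[2] for q in quads],
        LibraryKey("13C", oxygen, t0, "heavy"): [q[3] for q in quads],
    }
    data = {}
    for key, vals in cols.items():
        total = sum(vals)
        if total > 100:
            raise ValueError(f"quadruple column {key} exceeds 100%")
        data[key] = vals + [100.0 - total]
    df = pd.DataFrame(data, index=pd.Index(otus, name="otu_id"))
    return AbundanceTable(df, "percent")


def brute_force_verdict(
    ra: float, rb: float, rc: float, rd: float, T: float, *, require_c4: bool = False
) -> dict:
    """Direct, independent transcription of the four labeling criteria."""
    rcs = (3 * ra - rb - rc - rd) / 3
    c1 = ra - rb > T
    c2 = ra - rc > T
    c3 = ra - rd > T
    c4 = rcs > T
    labeled = c1 and c2 and c3 and (c4 if require_c4 else True)
    return {"c1": c1, "c2": c2, "c3": c3, "c4": c4, "r_cs": rcs, "labeled": labeled}
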
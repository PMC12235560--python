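"""Per-scan metadata record and conversions to/from tabular form."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

META_COLUMNS = ["scan_id", "subject_id", "age", "sex", "session", "rating", "euler_raw"]


@dataclass(frozen=True)
class ScanRecord:
    """Metadata for one scan.

    ``session`` is one of STAND/HM1/HM2 for repeated-session cohorts and
    ``None`` for single-scan training cohorts. ``rating`` is the 0-5 visual
    motion rating; ``euler_raw`` the raw (hemisphere-averaged) Euler number.
    """

    scan_id: str
    subject_id: str
    age: float
    sex: str
    session: Optional[str]
    rating: int
    euler_raw: float


def records_to_frame(records: Iterable[ScanRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=META_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[ScanRecord]:
    out = []
    for row in df.itertuples(index=False):
        session = row.session if isinstance(row.session, str) and row.session else None
        out.append(
            ScanRecord(
                scan_id=str(row.scan_id),
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=str(row.sex),
                session=session,
                rating=int(row.rating),
                euler_raw=float(row.euler_raw),
            )
        )
    return out
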
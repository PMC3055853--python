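from __future__ import annotations

from datetime import date, timedelta

import pytest

from dialclaims import ClaimDaySeries, ObservationWindow


@pytest.fixture
def window() -> ObservationWindow:
    return ObservationWindow(date(2008, 1, 1), date(2008, 12, 31))


ORIGIN = date(2008, 1, 1)


def series_from_offsets(offsets, patient_id="P1", origin=ORIGIN) -> ClaimDaySeries:
    """Build a claim-day series from day offsets relative to an origin date."""
    return ClaimDaySeries(
        patient_id, tuple(origin + timedelta(days=int(o)) for o in sorted(offsets))
    )


def brute_force_d4(offsets, span=90, max_gap=21) -> bool:
    """Independent oracle: enumerate every contiguous sub-run of claim days.

    A series qualifies iff some contiguous slice of the sorted day offsets
    has all successive gaps <= max_gap and last - first >= span.
    """
    days = sorted(offsets)
    for i in range(len(days)):
        for j in range(i, len(days)):
            run = days[i : j + 1]
            if all(y - x <= max_gap for x, y in zip(run, run[1:])):
                if run[-1] - run[0] >= span:
                    return True
    return False


def write_csv(path, header, rows) -> None:
    lines = [header] + [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
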
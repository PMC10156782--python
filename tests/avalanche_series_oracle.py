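"""Independent reference implementation of epoch extraction for oracle tests.

A deliberately simple one-pass scan over the series, written without numpy
vectorization so it shares no code path with the package implementation.
"""

from __future__ import annotations


def scan_runs_oracle(series) -> list[tuple[float, int]]:
    """(size, duration) of every positive run bounded by zeros on both sides.

    Runs touching either end of the series are excluded, matching the convention
    that an epoch whose bounding zero is unobserved has unknown extent.
    """
    out = []
    size = 0.0
    length = 0
    open_at_start = series[0] > 0
    for value in series:
        if value > 0:
            size += float(value)
            length += 1
        else:
            if length and not open_at_start:
                out.append((size, length))
            open_at_start = False
            size, length = 0.0, 0
    # a trailing run touches the right boundary: dropped
    return out
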
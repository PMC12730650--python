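"""Minimal 16-bit EDF writer, test-only.

Produces a standards-conformant EDF file (fixed-width ASCII header plus
little-endian int16 data records) so the package's EDF reader can be
exercised round-trip without an EDF-writing dependency.
"""

from __future__ import annotations

import numpy as np

PHYS_MIN, PHYS_MAX = -1000.0, 1000.0   # microvolts
DIG_MIN, DIG_MAX = -32768, 32767


def _field(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data_uv, fs, channel_labels):
    """Write channels x samples microvolt data as 16-bit EDF.

    Uses 1-second data records; the sample count must be a multiple of
    ``fs``. Quantization step is (PHYS_MAX-PHYS_MIN)/(DIG_MAX-DIG_MIN)
    ~= 0.0305 uV.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    ns, n_samples = data_uv.shape
    spr = int(fs)
    if n_samples % spr:
        raise ValueError("sample count must be a whole number of seconds")
    n_records = n_samples // spr

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.clip(np.round((data_uv - PHYS_MIN) * scale + DIG_MIN),
                      DIG_MIN, DIG_MAX).astype("<i2")

    hdr = b""
    hdr += _field("0", 8)                       # version
    hdr += _field("X X X X", 80)                # patient id
    hdr += _field("Startdate X X X X", 80)      # recording id
    hdr += _field("01.01.20", 8)                # start date
    hdr += _field("00.00.00", 8)                # start time
    hdr += _field(256 * (1 + ns), 8)            # header bytes
    hdr += _field("", 44)                       # reserved
    hdr += _field(n_records, 8)
    hdr += _field("1", 8)                       # record duration, s
    hdr += _field(ns, 4)

    def per_signal(vals, width):
        return b"".join(_field(v, width) for v in vals)

    hdr += per_signal(channel_labels, 16)
    hdr += per_signal(["AgAgCl electrode"] * ns, 80)
    hdr += per_signal(["uV"] * ns, 8)
    hdr += per_signal([f"{PHYS_MIN:g}"] * ns, 8)
    hdr += per_signal([f"{PHYS_MAX:g}"] * ns, 8)
    hdr += per_signal([DIG_MIN] * ns, 8)
    hdr += per_signal([DIG_MAX] * ns, 8)
    hdr += per_signal([""] * ns, 80)            # prefiltering
    hdr += per_signal([spr] * ns, 8)
    hdr += per_signal([""] * ns, 32)            # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())  # one signal after another
    return (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)
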
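"""Independent reference codec for the PLINK 1 .bed payload.

Written directly from the format definition using plain Python integer
arithmetic — deliberately sharing no code with the package's vectorized
lookup-table reader — so the two can serve as independent routes in
format-agreement tests.  Missing genotypes are returned as None.
"""

from __future__ import annotations

MAGIC = (0x6C, 0x1B)
VARIANT_MAJOR = 0x01

# bit pair -> allele-1 dosage; 0b01 is the missing code
_PAIR = {0b00: 2, 0b10: 1, 0b11: 0, 0b01: None}


def decode_bed_bytes(data: bytes, n_samples: int, n_variants: int) -> list[list]:
    """Decode a full .bed file into a samples x variants list-of-lists."""
    if data[0] != MAGIC[0] or data[1] != MAGIC[1]:
        raise ValueError("bad magic")
    if data[2] != VARIANT_MAJOR:
        raise ValueError("not variant-major")
    bpv = (n_samples + 3) // 4
    if len(data) != 3 + bpv * n_variants:
        raise ValueError("size mismatch")
    out = [[None] * n_variants for _ in range(n_samples)]
    for j in range(n_variants):
        record = data[3 + j * bpv: 3 + (j + 1) * bpv]
        for i in range(n_samples):
            byte = record[i // 4]
            pair = (byte >> (2 * (i % 4))) & 0b11
            out[i][j] = _PAIR[pair]
    return out


def encode_bed_bytes(geno: list[list]) -> bytes:
    """Encode a samples x variants list-of-lists (None = missing) as .bed."""
    n = len(geno)
    p = len(geno[0]) if n else 0
    rev = {v: k for k, v in _PAIR.items()}
    bpv = (n + 3) // 4
    payload = bytearray([MAGIC[0], MAGIC[1], VARIANT_MAJOR])
    for j in range(p):
        for byte_idx in range(bpv):
            byte = 0
            for k in range(4):
                i = 4 * byte_idx + k
                if i < n:
                    byte |= rev[geno[i][j]] << (2 * k)
            payload.append(byte)
    return bytes(payload)
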
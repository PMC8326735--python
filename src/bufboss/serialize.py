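"""Versioned binary serialization of the dynamic index state.

Single-file container, fixed little-endian layout:

    8 bytes   magic  b"BUFBOSS\\x01"
    4 bytes   manifest length (u32)
    ...       JSON manifest (version, k, sizes, flags)
    ...       binary payload: ebwt codes, degree arrays, deletion bits,
              addition-buffer entries
    4 bytes   CRC-32 of manifest + payload

Loading verifies the magic, the version, the CRC and the section sizes, so
truncated or corrupted files fail loudly.
"""

from __future__ import annotations

import json
import struct
import zlib
from pathlib import Path

import numpy as np

from .dynamic import AdditionEntry, BufBoss
from .index import BossIndex

MAGIC = b"BUFBOSS\x01"
VERSION = 1


class SerializationError(IOError):
    """The file is not a valid container (bad magic, version, CRC or size)."""


def save_state(state: BufBoss, path) -> None:
    """Write the index and both buffers to ``path`` (bit-exact round trip)."""
    boss = state.boss
    manifest = {
        "version": VERSION,
        "k": boss.k,
        "n_nodes": boss.n_nodes,
        "n_edges": boss.n_edges,
        "n_buffered": len(state.ha),
        "track_marks": state.marks is not None,
    }
    mbytes = json.dumps(manifest, sort_keys=True).encode()

    parts = [
        boss._ebwt.astype("<u1").tobytes(),
        boss.outdegrees.astype("<u4").tobytes(),
        boss.indegrees.astype("<u4").tobytes(),
        np.packbits(state.bd, bitorder="little").tobytes(),
        struct.pack("<Q", len(state.ha)),
    ]
    for label in sorted(state.ha):
        entry = state.ha[label]
        bits = 0
        for ch in label:
            bits = (bits << 2) | "ACGT".index(ch)
        parts.append(struct.pack("<BQBB", len(label), bits, entry.in_bits, entry.out_bits))
    payload = b"".join(parts)

    body = struct.pack("<I", len(mbytes)) + mbytes + payload
    crc = zlib.crc32(mbytes + payload) & 0xFFFFFFFF
    Path(path).write_bytes(MAGIC + body + struct.pack("<I", crc))


def load_state(path) -> BufBoss:
    """Read a container written by :func:`save_state`."""
    blob = Path(path).read_bytes()
    if len(blob) < len(MAGIC) + 8 or not blob.startswith(MAGIC):
        raise SerializationError(f"{path}: not a bufboss container")
    (stored_crc,) = struct.unpack("<I", blob[-4:])
    body = blob[len(MAGIC):-4]
    (mlen,) = struct.unpack("<I", body[:4])
    if len(body) < 4 + mlen:
        raise SerializationError(f"{path}: truncated manifest")
    mbytes, payload = body[4:4 + mlen], body[4 + mlen:]
    if zlib.crc32(mbytes + payload) & 0xFFFFFFFF != stored_crc:
        raise SerializationError(f"{path}: checksum mismatch")
    manifest = json.loads(mbytes)
    if manifest.get("version") != VERSION:
        raise SerializationError(f"{path}: unsupported version {manifest.get('version')}")

    k, n_nodes, n_edges = manifest["k"], manifest["n_nodes"], manifest["n_edges"]
    bd_bytes = (n_edges + 7) // 8
    need = n_edges + 8 * n_nodes + bd_bytes + 8
    if len(payload) < need:
        raise SerializationError(f"{path}: truncated payload")

    off = 0
    ebwt = np.frombuffer(payload, dtype="<u1", count=n_edges, offset=off); off += n_edges
    outdeg = np.frombuffer(payload, dtype="<u4", count=n_nodes, offset=off); off += 4 * n_nodes
    indeg = np.frombuffer(payload, dtype="<u4", count=n_nodes, offset=off); off += 4 * n_nodes
    bd = np.unpackbits(
        np.frombuffer(payload, dtype=np.uint8, count=bd_bytes, offset=off),
        bitorder="little", count=n_edges).astype(bool)
    off += bd_bytes
    (n_ha,) = struct.unpack_from("<Q", payload, off); off += 8

    boss = BossIndex(k, ebwt, outdeg.astype(np.int64), indeg.astype(np.int64))
    state = BufBoss(boss, track_marks=manifest.get("track_marks", False))
    state.bd = bd
    for _ in range(n_ha):
        if off + 11 > len(payload):
            raise SerializationError(f"{path}: truncated buffer section")
        length, bits, in_bits, out_bits = struct.unpack_from("<BQBB", payload, off)
        off += 11
        chars = []
        for _i in range(length):
            chars.append("ACGT"[bits & 3])
            bits >>= 2
        label = "".join(reversed(chars))
        state.ha[label] = AdditionEntry(in_bits, out_bits)
        if state.marks is not None:
            state._mark_label(label)
    if state.marks is not None and n_edges:
        for r in np.flatnonzero(bd) + 1:
            state._mark_rank(boss.forward_edge(int(r)))
    return state
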
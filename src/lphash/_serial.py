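"""Little-endian binary serialization helpers.

All persistent structures in the package are written through these two
classes: fixed-width integers are little-endian, variable-length payloads
carry a u64 length prefix, and every read failure reports the byte offset
at which it occurred.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError


class ByteWriter:
    def __init__(self) -> None:
        self._parts: list[bytes] = []

    def u8(self, v: int) -> None:
        self._parts.append(struct.pack("<B", v))

    def u16(self, v: int) -> None:
        self._parts.append(struct.pack("<H", v))

    def u32(self, v: int) -> None:
        self._parts.append(struct.pack("<I", v))

    def u64(self, v: int) -> None:
        self._parts.append(struct.pack("<Q", v))

    def raw(self, data: bytes) -> None:
        self._parts.append(data)

    def blob(self, data: bytes) -> None:
        """Length-prefixed byte string."""
        self.u64(len(data))
        self._parts.append(data)

    def u64_array(self, arr: np.ndarray) -> None:
        self.blob(np.ascontiguousarray(arr, dtype="<u8").tobytes())

    def getvalue(self) -> bytes:
        return b"".join(self._parts)


class ByteReader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def take(self, n: int, what: str = "data") -> bytes:
        if self.pos + n > len(self.data):
            raise FormatError(
                f"truncated input: needed {n} bytes of {what} at offset "
                f"{self.pos}, only {len(self.data) - self.pos} available"
            )
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self, what: str = "u8") -> int:
        return struct.unpack("<B", self.take(1, what))[0]

    def u16(self, what: str = "u16") -> int:
        return struct.unpack("<H", self.take(2, what))[0]

    def u32(self, what: str = "u32") -> int:
        return struct.unpack("<I", self.take(4, what))[0]

    def u64(self, what: str = "u64") -> int:
        return struct.unpack("<Q", self.take(8, what))[0]

    def blob(self, what: str = "blob") -> bytes:
        n = self.u64(what + " length")
        return self.take(n, what)

    def u64_array(self, what: str = "array") -> np.ndarray:
        raw = self.blob(what)
        if len(raw) % 8:
            raise FormatError(
                f"corrupt {what}: byte length {len(raw)} not a multiple of 8 "
                f"at offset {self.pos}"
            )
        return np.frombuffer(raw, dtype="<u8").astype(np.uint64)

    def expect_end(self) -> None:
        if self.pos != len(self.data):
            raise FormatError(
                f"{len(self.data) - self.pos} unexpected trailing bytes at "
                f"offset {self.pos}"
            )
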
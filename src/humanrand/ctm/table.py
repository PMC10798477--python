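"""Packaged Coding-Theorem complexity table for binary strings up to length 12.

The packaged resource ``ctm_b2_d12_synthetic.tsv`` is a synthetic stand-in
for the published 5-state Coding-Theorem table: it was computed from scratch
by exhaustive enumeration of the 4-state binary Turing-machine space (see
``humanrand.ctm.enumerate`` and ``scripts/build_ctm_table.py``), with
lengths beyond the enumeration's complete coverage filled in by the
minimal-split concatenation rule.  Values are algorithmic-complexity
estimates in bits; within each length, lower means simpler, and the
constant strings are the minima.

The table is exactly symmetric under global bit complement and reversal,
so the TSV stores one canonical representative per symmetry class and the
loader expands it to all 8190 strings of lengths 1-12.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ..errors import ConfigurationError, DomainError, ValidationError

log = logging.getLogger(__name__)

MAX_LEN = 12
DEFAULT_RESOURCE = "ctm_b2_d12_synthetic"

_BINARY = frozenset("01")


def complement(s: str) -> str:
    return s.translate(str.maketrans("01", "10"))


def canonical_key(s: str) -> str:
    """Lexicographically smallest of {s, reverse, complement, both}."""
    r = s[::-1]
    c = complement(s)
    return min(s, r, c, c[::-1])


@dataclass(frozen=True)
class CTMTable:
    """Lookup of algorithmic-complexity values (bits) for binary strings."""

    entries: dict[str, float]
    source_label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths: dict[int, int] = {}
        for s, v in self.entries.items():
            if not s or len(s) > MAX_LEN or set(s) - _BINARY:
                raise ValidationError(f"illegal table key {s!r}")
            if not (v > 0 and v < float("inf")):
                raise ValidationError(f"non-finite or non-positive value for {s!r}")
            lengths[len(s)] = lengths.get(len(s), 0) + 1
        for n, count in sorted(lengths.items()):
            if count != 2**n:
                raise ValidationError(
                    f"length {n} incomplete: {count} of {2 ** n} strings present"
                )
        bad = sum(
            1
            for s, v in self.entries.items()
            if abs(v - self.entries[complement(s)]) > 1e-12
        )
        if bad:
            # tolerated (empirical tables need not be exactly symmetric),
            # but worth surfacing: complement-invariance tests rely on it
            log.warning("complement symmetry violated for %d entries", bad)
        lo: dict[int, float] = {}
        hi: dict[int, float] = {}
        for s, v in self.entries.items():
            n = len(s)
            if v < lo.get(n, float("inf")):
                lo[n] = v
            if v > hi.get(n, float("-inf")):
                hi[n] = v
        object.__setattr__(self, "_len_min", lo)
        object.__setattr__(self, "_len_max", hi)

    @property
    def lengths(self) -> list[int]:
        return sorted({len(s) for s in self.entries})

    def value(self, s: str) -> float:
        """Exact CTM lookup in bits; strings of length 1..12 only."""
        if not s or set(s) - _BINARY:
            raise DomainError(f"not a non-empty binary string: {s!r}")
        if len(s) > MAX_LEN:
            raise DomainError(
                f"string of length {len(s)} exceeds the table maximum {MAX_LEN}"
            )
        return self.entries[s]

    def length_min(self, n: int) -> float:
        return self._len_min[n]  # type: ignore[attr-defined]

    def length_max(self, n: int) -> float:
        return self._len_max[n]  # type: ignore[attr-defined]


def _all_strings(n: int):
    for bits in range(1 << n):
        yield format(bits, f"0{n}b")


def ctm(s: str, table: CTMTable) -> float:
    """Coding-Theorem complexity of ``s`` in bits (exact table lookup)."""
    return table.value(s)


def _data_dir():
    return resources.files("humanrand.ctm") / "data"


def write_table(entries: dict[str, float], path: str | Path, source_label: str,
                meta: dict | None = None) -> None:
    """Write a table as a canonical-key TSV plus a checksum manifest."""
    path = Path(path)
    canon: dict[str, float] = {}
    for s, v in entries.items():
        k = canonical_key(s)
        prev = canon.get(k)
        if prev is not None and abs(prev - v) > 1e-9:
            raise ValidationError(
                f"entries are not symmetry-consistent at {k!r}: {prev} vs {v}"
            )
        canon[k] = v
    lines = ["string\tvalue\n"]
    for k in sorted(canon, key=lambda s: (len(s), s)):
        lines.append(f"{k}\t{canon[k]:.10f}\n")
    body = "".join(lines).encode()
    path.write_bytes(body)
    manifest = {
        "resource": path.name,
        "source_label": source_label,
        "sha256": hashlib.sha256(body).hexdigest(),
        "n_canonical_entries": len(canon),
        **(meta or {}),
    }
    path.with_suffix(".manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n"
    )


def load_ctm_table(resource_name: str | Path = DEFAULT_RESOURCE) -> CTMTable:
    """Load and validate a packaged (or on-disk) CTM table.

    ``resource_name`` is either the bare name of a packaged resource or a
    path to a ``.tsv`` written by :func:`write_table`.
    """
    p = Path(str(resource_name))
    if p.suffix == ".tsv" and p.exists():
        tsv, manifest_path = p, p.with_suffix(".manifest.json")
        raw = tsv.read_bytes()
        manifest = (
            json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
        )
    else:
        node = _data_dir() / f"{resource_name}.tsv"
        try:
            raw = node.read_bytes()
        except (FileNotFoundError, ModuleNotFoundError) as exc:
            raise ConfigurationError(
                f"packaged CTM table {resource_name!r} not found"
            ) from exc
        mnode = _data_dir() / f"{resource_name}.manifest.json"
        try:
            manifest = json.loads(mnode.read_text())
        except FileNotFoundError:
            manifest = {}
    if manifest.get("sha256"):
        digest = hashlib.sha256(raw).hexdigest()
        if digest != manifest["sha256"]:
            raise ValidationError(
                f"checksum mismatch for {resource_name}: {digest} != "
                f"{manifest['sha256']}"
            )
    entries: dict[str, float] = {}
    lines = raw.decode().splitlines()
    if not lines or lines[0].split("\t") != ["string", "value"]:
        raise ValidationError("corrupt table: missing 'string\\tvalue' header")
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"corrupt table at line {i}: {line!r}")
        s, sval = parts
        if not s or set(s) - _BINARY:
            raise ValidationError(f"corrupt table at line {i}: bad string {s!r}")
        try:
            v = float(sval)
        except ValueError as exc:
            raise ValidationError(f"corrupt table at line {i}: bad value") from exc
        r, c = s[::-1], complement(s)
        for variant in {s, r, c, c[::-1]}:
            entries[variant] = v
    return CTMTable(
        entries=entries,
        source_label=manifest.get("source_label", str(resource_name)),
        meta=manifest,
    )
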
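"""Gene-set collections and the GMT file format (set id, description, members)."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneSetCollection:
    """Pathway id -> (description, member feature ids)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {pid!r} is empty")
        self.sets = {pid: frozenset(m) for pid, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pid: str) -> bool:
        return pid in self.sets

    def members(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    def description(self, pid: str) -> str:
        return self.descriptions.get(pid, "")

    def sets_of(self, feature: str) -> set[str]:
        return {pid for pid, m in self.sets.items() if feature in m}

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping sets that become empty."""
        kept = {
            pid: m & frozenset(universe)
            for pid, m in self.sets.items()
            if m & frozenset(universe)
        }
        return GeneSetCollection(kept, {p: self.description(p) for p in kept})

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid in sorted(self.sets):
                members = "\t".join(sorted(self.sets[pid]))
                fh.write(f"{pid}\t{self.description(pid)}\t{members}\n")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        desc: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line!r}")
                pid, d, members = parts[0], parts[1], [m for m in parts[2:] if m]
                if pid in sets:
                    raise ValueError(f"duplicate gene-set id {pid!r}")
                sets[pid] = frozenset(members)
                desc[pid] = d
        return cls(sets, desc)
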
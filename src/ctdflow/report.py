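"""Machine-readable record of what a conversion did.

Every converter in the toolkit returns one of these next to its artifact:
which source constructs were mapped (and to what), which were dropped with
a reason, and which caused outright rejection.  A conversion is rejected
exactly when the rejection list is non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ConversionReport:
    status: str = "converted"  # "converted" | "rejected"
    mapped: list = field(default_factory=list)  # (source, target, mapping)
    dropped: list = field(default_factory=list)  # (source, reason)
    rejections: list = field(default_factory=list)  # construct tags

    def reject(self, tag: str) -> None:
        if tag not in self.rejections:
            self.rejections.append(tag)
        self.status = "rejected"

    def finalize(self) -> "ConversionReport":
        self.status = "rejected" if self.rejections else "converted"
        return self

    def to_text(self) -> str:
        lines = [f"status: {self.status}"]
        for src, target, mapping in self.mapped:
            lines.append(f"mapped: {src} -> {target} ({mapping})")
        for src, reason in self.dropped:
            lines.append(f"dropped: {src} ({reason})")
        for tag in self.rejections:
            lines.append(f"rejected: {tag}")
        return "\n".join(lines) + "\n"
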
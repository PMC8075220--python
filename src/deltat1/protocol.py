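"""MP2RAGE sequence timing and flip-angle parameters.

The MP2RAGE sequence plays one adiabatic inversion per cycle of length
``tr_mp2rage`` and reads out two turbo-GRE blocks of ``n_exc`` low-flip-angle
excitations each, centred on the two inversion times ``ti1`` and ``ti2``.
These parameters fully determine the steady-state signal model and hence the
UNI-to-T1 lookup table.  The default constructor reproduces the 7 T protocol
this package was written around (8.5 s cycle, TI 1.0/3.0 s, 5deg/5deg,
turbo factor 252, echo spacing 6.9 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

from .exceptions import ConfigurationError

__all__ = ["SequenceProtocol"]


@dataclass(frozen=True)
class SequenceProtocol:
    """Timing and flip-angle parameters of an MP2RAGE acquisition.

    All times are in seconds, flip angles in degrees.  ``inv_eff`` is the
    inversion efficiency in (0, 1]; 1.0 means a perfect 180deg inversion.
    """

    tr_mp2rage: float = 8.5
    ti1: float = 1.0
    ti2: float = 3.0
    alpha1: float = 5.0
    alpha2: float = 5.0
    n_exc: int = 252
    tr_gre: float = 0.0069
    inv_eff: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ti1 < self.ti2 < self.tr_mp2rage):
            raise ConfigurationError(
                f"require 0 < ti1 < ti2 < tr_mp2rage, got "
                f"ti1={self.ti1}, ti2={self.ti2}, tr={self.tr_mp2rage}"
            )
        if self.n_exc < 1 or self.n_exc % 2:
            raise ConfigurationError("n_exc must be a positive even turbo factor")
        if self.tr_gre <= 0:
            raise ConfigurationError("tr_gre must be positive")
        if not (0.0 < self.inv_eff <= 1.0):
            raise ConfigurationError("inv_eff must lie in (0, 1]")
        half = self.n_exc / 2 * self.tr_gre
        if self.ti1 - half < 0 or self.ti2 + half > self.tr_mp2rage:
            raise ConfigurationError(
                "GRE blocks do not fit inside the cycle: need "
                "ti1 - (n_exc/2)*tr_gre >= 0 and ti2 + (n_exc/2)*tr_gre <= tr_mp2rage"
            )
        if self.ti2 - half < self.ti1 + half:
            raise ConfigurationError("GRE blocks overlap between ti1 and ti2")

    # Free-relaxation gap durations of one cycle: inversion -> block1 -> block2 -> end.
    @property
    def ta(self) -> float:
        """Gap between inversion and the first excitation of block 1 (s)."""
        return self.ti1 - self.n_exc / 2 * self.tr_gre

    @property
    def tb(self) -> float:
        """Gap between the end of block 1 and the start of block 2 (s)."""
        return self.ti2 - self.ti1 - self.n_exc * self.tr_gre

    @property
    def tc(self) -> float:
        """Gap between the end of block 2 and the next inversion (s)."""
        return self.tr_mp2rage - self.ti2 - self.n_exc / 2 * self.tr_gre

    @classmethod
    def from_file(cls, path: str | Path) -> "SequenceProtocol":
        """Read a protocol from a plain-text ``key = value`` file (SI units)."""
        fields: dict[str, float] = {}
        known = {f for f in cls.__dataclass_fields__}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigurationError(f"{path}:{lineno}: unknown protocol field {key!r}")
            fields[key] = float(value)
        if "n_exc" in fields:
            fields["n_exc"] = int(fields["n_exc"])  # type: ignore[assignment]
        return cls(**fields)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        """Write the protocol as a ``key = value`` file readable by ``from_file``."""
        lines = [f"{key} = {value}" for key, value in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")
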
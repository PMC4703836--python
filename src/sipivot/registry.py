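"""Built-in guide strands used throughout the package's tests and examples.

These are widely used laboratory duplexes written in standard oligo notation:
siRL targets the Renilla luciferase gene (a common reporter control), the
siPCSK9 pair targets PCSK9 (a hypercholesterolemia drug target; the A2 form
adds stabilizing 2'-OMe groups), siMAPK14 targets MAPK14/p38a, and the
miRNAs (miR-124, miR-708, cel-miR-67) are synthesized with their miRBase
sequences.  The non-targeting control (NT) derives from cel-miR-67 with
2'-OMe at positions 1-2 of both strands.
"""

from __future__ import annotations

from .guides import ModifiedGuide, parse_guide_string

_GUIDE_STRINGS: dict[str, tuple[str, str]] = {
    # name: (guide notation, passenger notation or "")
    "siRL": ("5′p-GUAGGAGUAGUGAAAGGCCdTdT-3′", "5′p-GGCCUUUCACUACUCCUACdTdT-3′"),
    "siPCSK9-A1": ("5′-UUCCGAAUAAACUCCAGGCdTdT-3′", "5′p-GCCUGGAGUUUAUUCGGAAdTdT-3′"),
    "siPCSK9-A2": ("5′p-UUCCGAAuAAACUCcAGGCdTdT-3′", "5′-GccuGGAGuuuAuucGGAAdTdT-3′"),
    "siMAPK14": ("5′p-AACCGCAGUUCUCUGUAGGdTdT-3′", "5′p-CCUACAGAGAACUGCGGUUdTdT-3′"),
    "miR-124": ("UAAGGCACGCGGUGAAUGCC", ""),
    "miR-708": ("AAGGAGCUUACAAUCUAGCUGGG", ""),
    "cel-miR-67": ("UCACAACCUCCUAGAAAGAGUAGA", ""),
    "NT": ("5′p-uaCUCUUUCUAGGAGGUUGUGAdTdT-3′", "5′p-ucACAACCUCCUAGAAAGAGUAdTdT-3′"),
}


def get_guide(name: str, strand: str = "guide") -> ModifiedGuide:
    """Look up a built-in guide (or its passenger) by name."""
    try:
        guide_str, passenger_str = _GUIDE_STRINGS[name]
    except KeyError:
        raise KeyError(
            f"unknown guide {name!r}; available: {sorted(_GUIDE_STRINGS)}"
        ) from None
    if strand == "guide":
        return parse_guide_string(guide_str, name=name, role="guide")
    if strand == "passenger":
        if not passenger_str:
            raise ValueError(f"no passenger strand recorded for {name!r}")
        return parse_guide_string(passenger_str, name=f"{name}*", role="passenger")
    raise ValueError(f"strand must be guide or passenger, got {strand!r}")


def available_guides() -> list[str]:
    return sorted(_GUIDE_STRINGS)
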
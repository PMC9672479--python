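"""Feature-name rendering, parsing, and the nine-group taxonomy.

A full series feature name is ``<filter>_<family>_<base>_<n>`` where
``filter`` is ``original``, ``log-sigma-<s>-mm-3D`` or ``wavelet-<band>``,
``family`` is one of the seven radiomics families, ``base`` is the feature
base name (CamelCase, no underscores) and ``n`` is the 0-based timepoint
index of the 3D image the feature was computed on.  Parsing is the exact
inverse of rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FeatureName", "FAMILIES", "GROUPS", "group_of", "parse_name"]

FAMILIES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

#: The nine reporting groups: seven families on the original image plus
#: the two filter groups, which subsume every family computed on a
#: filtered image.
GROUPS = (
    "Shape", "First-order", "GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDM",
    "Log-sigma", "Wavelet",
)

_FAMILY_GROUP = {
    "shape": "Shape", "firstorder": "First-order", "glcm": "GLCM",
    "glrlm": "GLRLM", "glszm": "GLSZM", "ngtdm": "NGTDM", "gldm": "GLDM",
}


@dataclass(frozen=True)
class FeatureName:
    filter_tag: str      # "original", "log-sigma-1-0-mm-3D", "wavelet-LLH"
    family: str          # one of FAMILIES
    base_name: str       # e.g. "Skewness"
    time_index: int      # 0-based timepoint n

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if "_" in self.filter_tag or "_" in self.base_name:
            raise ValueError("filter and base names must not contain '_'")
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")

    def render(self) -> str:
        return f"{self.filter_tag}_{self.family}_{self.base_name}_{self.time_index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_name(name: str) -> FeatureName:
    """Parse ``<filter>_<family>_<base>_<n>`` back into a FeatureName."""
    parts = name.split("_")
    if len(parts) != 4:
        raise ValueError(f"cannot parse feature name {name!r}")
    filt, family, base, n = parts
    if family not in FAMILIES:
        raise ValueError(f"unknown family in {name!r}")
    if not _valid_filter(filt):
        raise ValueError(f"unknown filter tag in {name!r}")
    return FeatureName(filt, family, base, int(n))


def _valid_filter(tag: str) -> bool:
    return (
        tag == "original"
        or tag.startswith("log-sigma-")
        or tag.startswith("wavelet-")
    )


def log_sigma_tag(sigma_mm: float) -> str:
    """Render a LoG filter tag, e.g. 1.0 -> 'log-sigma-1-0-mm-3D'."""
    s = f"{float(sigma_mm):g}"
    if "." not in s:
        s += ".0"
    return f"log-sigma-{s.replace('.', '-')}-mm-3D"


def group_of(name: FeatureName | str) -> str:
    """Map a feature name to its reporting group.

    Filter tags dominate the family: any feature computed on a LoG or
    wavelet image belongs to the Log-sigma or Wavelet group regardless of
    its family.
    """
    if isinstance(name, str):
        name = parse_name(name)
    if name.filter_tag.startswith("log-sigma"):
        return "Log-sigma"
    if name.filter_tag.startswith("wavelet"):
        return "Wavelet"
    if name.filter_tag == "original":
        return _FAMILY_GROUP[name.family]
    raise ValueError(f"unknown filter tag {name.filter_tag!r}")
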
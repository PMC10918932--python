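"""Clinical-severity categorisation from condition flags.

Patients are placed in one of three categories from the condition codes on
their attribute record: *severe* when carrying a chronic mental-health
condition, *moderate* when carrying only an associated condition, *mild*
otherwise.

Two incompatible code-to-category mappings circulate for this cohort: one
treats depression, PTSD and eating disorder as the chronic (severe) set with
autism, ADHD and dependency conditions as associated (moderate); the other
reverses those roles.  Both ship here as named configurations and the
classifier takes the configuration explicitly -- the package does not
endorse either as a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SeverityConfig:
    """A code-to-category mapping for :func:`classify_severity`.

    ``severe`` and ``moderate`` are disjoint sets of condition codes; any
    code in neither set is treated as unknown (see ``strict``).
    """

    name: str
    severe: frozenset[str]
    moderate: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.severe & self.moderate
        if overlap:
            raise ValueError(f"codes in both severe and moderate sets: {sorted(overlap)}")

    @property
    def known_codes(self) -> frozenset[str]:
        return self.severe | self.moderate


#: Mapping with depression/PTSD/eating disorder etc. as the chronic (severe)
#: conditions and dependency/neurodevelopmental conditions as associated.
SEVERITY_METHODS_TEXT = SeverityConfig(
    name="methods_text",
    severe=frozenset(
        {
            "depression",
            "ptsd",
            "eating_disorder",
            "bipolar_disorder",
            "schizophrenia",
            "anxiety",
        }
    ),
    moderate=frozenset(
        {"drug_dependency", "alcohol_dependency", "autism", "adhd", "addiction"}
    ),
)

#: The reversed mapping: autism/ADHD/addiction as severe, common mental-health
#: diagnoses as moderate.
SEVERITY_TABLE2_FOOTNOTES = SeverityConfig(
    name="table2_footnotes",
    severe=frozenset({"autism", "adhd", "addiction", "drug_dependency", "alcohol_dependency"}),
    moderate=frozenset(
        {"depression", "anxiety", "eating_disorder", "ptsd", "bipolar_disorder", "schizophrenia"}
    ),
)

SEVERITY_CONFIGS: dict[str, SeverityConfig] = {
    c.name: c for c in (SEVERITY_METHODS_TEXT, SEVERITY_TABLE2_FOOTNOTES)
}

CATEGORIES = ("severe", "moderate", "mild")


def classify_severity(
    condition_flags,
    config: SeverityConfig,
    *,
    strict: bool = False,
) -> str:
    """Categorise a patient's severity from their set of condition codes.

    Parameters
    ----------
    condition_flags
        Iterable of condition codes (order-irrelevant; duplicates ignored).
    config
        Which code-to-category mapping to apply.
    strict
        If True, raise ``ValueError`` on a code outside the configured lists;
        otherwise unknown codes are ignored.

    Returns
    -------
    str
        ``"severe"`` if any chronic code is present, else ``"moderate"`` if
        any associated code is present, else ``"mild"``.
    """
    flags = frozenset(condition_flags)
    unknown = flags - config.known_codes
    if unknown and strict:
        raise ValueError(f"unknown condition codes {sorted(unknown)} under config {config.name!r}")
    if flags & config.severe:
        return "severe"
    if flags & config.moderate:
        return "moderate"
    return "mild"
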
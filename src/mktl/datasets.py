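"""Packaged data sets."""

from __future__ import annotations

from importlib import resources

from .distribution import Sample

__all__ = ["load_covid_mortality"]


def load_covid_mortality() -> Sample:
    """The 27 Saudi Arabia COVID-19 daily mortality rates (Aug 4-30, 2021).

    Daily deaths expressed as rates in (0, 1); the worked real-data
    application for the MKTL model.
    """
    path = resources.files("mktl").joinpath("data/saudi_covid_mortality.txt")
    values = [
        float(line)
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return Sample(values)
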
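"""Bundled datasets."""

from importlib import resources

from .io import CohortTable, read_cohort

__all__ = ["load_reference_cohort"]


def load_reference_cohort() -> CohortTable:
    """The bundled reference glioma cohort (n = 37).

    Per-patient histology, IDH1 immunostaining status, WHO grade,
    centroid proportions and conventional dynamic FET-PET parameters for
    37 treatment-naive glioma patients, transcribed from a published
    clinical table.  Survival columns are absent (per-patient follow-up
    times are not public); cohort-level survival behavior is exercised
    with :func:`fetclust.synthetic.simulate_cohort` instead.
    """
    path = resources.files("fetclust").joinpath("data/reference_cohort.csv")
    with resources.as_file(path) as p:
        return read_cohort(p)
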
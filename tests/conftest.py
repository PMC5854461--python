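import numpy as np
import pytest

from fpem import (
    CountryMeta,
    Dataset,
    PopulationCount,
    ServiceStatObservation,
    SurveyObservation,
)


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two countries in one subregion with a handful of observations."""
    meta = [
        CountryMeta("AAA", "Alphaland", "Subregion 1", "Region 1", True),
        CountryMeta("BBB", "Betaland", "Subregion 1", "Region 1", False),
    ]
    surveys = [
        SurveyObservation("AAA", "total_cpr", 0.30, "DHS", 2000.5, 2000.5, 0.01),
        SurveyObservation("AAA", "modern_cpr", 0.22, "DHS", 2000.5, 2000.5, 0.01),
        SurveyObservation("AAA", "unmet_any", 0.25, "DHS", 2000.5, 2000.5, 0.012),
        SurveyObservation("AAA", "total_cpr", 0.38, "MICS", 2009.5, 2010.5, None),
        SurveyObservation("BBB", "total_cpr", 0.45, "NATIONAL", 2005.5, 2005.5, 0.02),
        SurveyObservation("BBB", "modern_cpr", 0.35, "DHS", 2011.5, 2012.5, 0.015),
    ]
    service = [
        ServiceStatObservation("BBB", 2013.5, 0.36),
        ServiceStatObservation("BBB", 2014.5, 0.38),
        ServiceStatObservation("BBB", 2015.5, 0.40),
    ]
    pops = [
        PopulationCount(code, year, mwra)
        for code, mwra in (("AAA", 1_000_000.0), ("BBB", 2_500_000.0))
        for year in range(1990, 2021)
    ]
    return Dataset(surveys=surveys, service_stats=service, meta=meta, populations=pops)
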
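import warnings

import pytest

from coixpep import AminoAcidProfile, load_table3_profiles

# printed derived rows of the composition table, for reproduction tests
# (fresh-content rows F and F/T are excluded: the printed F row equals Asp
# alone, inconsistent with the fresh class {Glu, Asp} used throughout)
PRINTED_TABLE3 = {
    "raw": {
        "taa": 102.66, "eaa": 35.31, "neaa": 67.345, "haa": 53.50,
        "b": 36.14, "s": 19.96, "d": 77.33,
        "eaa_taa": 34.40, "eaa_neaa": 52.43,
        "b_t": 35.20, "s_t": 19.45, "d_t": 75.33,
        "tft": 969.44, "tbt": 472.04, "tst": 45.19,
        "per1": 6.96, "per2": 7.02, "per3": 8.11,
    },
    "stir_frying": {
        "taa": 101.96, "eaa": 34.74, "neaa": 67.22, "haa": 53.17,
        "b": 35.78, "s": 20.06, "d": 77.08,
        "eaa_taa": 34.07, "eaa_neaa": 51.68,
        "b_t": 35.09, "s_t": 19.68, "d_t": 75.59,
        "tft": 963.13, "tbt": 475.80, "tst": 45.95,
        "per1": 6.89, "per2": 6.96, "per3": 8.18,
    },
    "bran_stir_frying": {
        "taa": 100.52, "eaa": 34.44, "neaa": 66.08, "haa": 52.50,
        "b": 35.33, "s": 19.58, "d": 75.77,
        "eaa_taa": 34.27, "eaa_neaa": 52.12,
        "b_t": 35.15, "s_t": 19.48, "d_t": 75.38,
        "tft": 946.90, "tbt": 460.31, "tst": 44.45,
        "per1": 6.76, "per2": 6.83, "per3": 7.83,
    },
}


def make_profile(sample: str) -> AminoAcidProfile:
    """Build an AminoAcidProfile from a packaged composition column."""
    table = load_table3_profiles()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # only 17 of 20 residues measured
        return AminoAcidProfile(sample_id=sample, content=table[sample].to_dict())


@pytest.fixture(scope="session")
def raw_profile() -> AminoAcidProfile:
    """Amino-acid profile of the unprocessed (raw) prolamin sample."""
    return make_profile("raw")
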
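"""Bundled data: the published specimen-level morphology matrix.

The packaged table transcribes the printed data matrix for the wasp
*Cryptoxenodon metamorphus*: 29 specimens (28 ingroup females plus one
*Diapetimorpha* outgroup, marked ``*``), each with collection country,
altitude in meters, DMS latitude, and 24 single-digit morphological
character states.  One latitude carries an invalid seconds field
(``69.0``) exactly as printed; the DMS parser carries it over with a
warning.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

#: characters run as ordered (additive) in the published delimitation analysis
PUBLISHED_ADDITIVE = (0, 2, 3, 5, 6, 11, 12, 13, 14, 15, 17, 21, 22, 23)

#: concavity constant used for the published implied-weights search
PUBLISHED_K = 4.765625

#: characters replaced by RGB sample points in the combined matrix, and the
#: sample points (numbering of the published sampling scheme) equivalent to them
RGB_EQUIVALENT_CHARACTERS = (5, 6, 8, 10, 19, 20, 21, 22, 23)
RGB_EQUIVALENT_POINTS = (3, 4, 6, 7, 8, 9, 10, 11, 15, 18, 24, 25)


def load_specimen_matrix() -> pd.DataFrame:
    """Load the packaged 29-specimen x 24-character morphology table.

    Returns the parsed specimen table (see
    :func:`morphocline.io.read_specimen_table`): one row per specimen with
    ``specimen_id``, ``outgroup``, ``altitude_m``, ``latitude_deg`` and
    ``char_00 .. char_23`` columns.
    """
    from morphocline.io import read_specimen_table

    ref = resources.files("morphocline") / "data" / "cryptoxenodon_specimens.tsv"
    with resources.as_file(ref) as path, warnings.catch_warnings():
        # the one printed invalid-seconds latitude is expected
        warnings.simplefilter("ignore")
        return read_specimen_table(path)
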
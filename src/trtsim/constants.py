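"""Physical constants and unit conversions.

The whole package works in a single normalized unit system so that the
standard parameter table applies verbatim:

* time in days,
* volumes in ml,
* amounts of antibodies / receptors / nuclides in pmol,
* concentrations in nM (= pmol/ml),
* cell counts in units of 1e7 cells.

Radioactivity appears only at I/O boundaries, converted through the single
instantaneous-activity relation ``activity = n_molecules * lambda_per_second``.
"""

from scipy.constants import Avogadro

#: molecules per pmol
AVOGADRO_PER_PMOL: float = Avogadro * 1e-12

#: 1 nCi in Bq (decays per second)
BQ_PER_NCI: float = 37.0

SECONDS_PER_DAY: float = 86400.0

#: IgG1 antibody molar mass in g/mol, used for labeling-ratio conversions
IGG_MOLAR_MASS_G_PER_MOL: float = 148_000.0
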
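"""Gene-symbol reference lists used throughout demos and simulations.

The 25 human selenoproteins: five glutathione peroxidases, three
iodothyronine deiodinases, three thioredoxin reductases, and the
remaining SELENO*/MSRB1/SEPHS2 members.
"""

SELENOPROTEINS: tuple[str, ...] = (
    "DIO1", "DIO2", "DIO3",
    "GPX1", "GPX2", "GPX3", "GPX4", "GPX6",
    "MSRB1",
    "SELENOF", "SELENOH", "SELENOI", "SELENOK", "SELENOM", "SELENON",
    "SELENOO", "SELENOP", "SELENOS", "SELENOT", "SELENOV", "SELENOW",
    "SEPHS2",
    "TXNRD1", "TXNRD2", "TXNRD3",
)

#: Housekeeping gene used to normalise qPCR quantification cycles.
HOUSEKEEPING_GENE = "ACTB"

#: The two markers whose coordinated expression the pipeline evaluates.
BIOMARKER_PAIR = ("SELENOS", "VCP")

assert len(SELENOPROTEINS) == 25
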
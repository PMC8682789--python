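"""Published benchmark rows: known and novel prophages with their four
att coordinates and the reported size / att-core length.

name, reference sequence, attL_start, attL_end, attR_start, attR_end,
size (bp), att length (bp).
"""

KNOWN_PROPHAGES = [
    ("Pf4", "NC_002516.2", 785288, 785336, 797699, 797747, 12411, 49),
    ("CP4So", "NC_004347.2", 1501853, 1501946, 1538064, 1538157, 36211, 94),
    ("LambdaSo", "NC_004347.2", 3074594, 3074605, 3126435, 3126446, 51841, 12),
    ("rac", "NZ_CP009273.1", 1406156, 1406198, 1429216, 1429258, 23060, 43),
    ("Phi10403S", "NC_017544.1", 2319845, 2319847, 2357456, 2357458, 37611, 3),
]

CORAL_PROPHAGES = [
    ("Pea1", "SCSIO_43205", 1888722, 1888741, 1936851, 1936870, 48129, 20),
    ("Prc1", "SCSIO_43209", 1373446, 1373460, 1379997, 1380011, 6551, 15),
    ("Phm1", "SCSIO_43005", 292609, 292683, 333351, 333425, 40742, 75),
    ("Phm2", "SCSIO_43005", 1064123, 1064145, 1100156, 1100178, 36033, 23),
    ("Phm3", "SCSIO_43005", 2090511, 2090576, 2139945, 2140010, 49434, 66),
    ("Pvn1", "SCSIO_43132", 353280, 353303, 367745, 367768, 14465, 24),
    ("Pmo1", "SCSIO_43207", 2643352, 2643371, 2676198, 2676217, 32846, 20),
    ("Pms1", "SCSIO_43206", 2668021, 2668042, 2679241, 2679262, 11220, 22),
    ("Pzm1", "SCSIO_43204", 1472262, 1472314, 1512357, 1512409, 40095, 53),
]

ALL_ROWS = KNOWN_PROPHAGES + CORAL_PROPHAGES
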
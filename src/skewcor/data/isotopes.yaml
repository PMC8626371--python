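# Natural isotope reference table.
#
# Per element: a list of stable isotopes with exact mass (Da) and natural
# abundance (mole fraction).  Values follow the standard atomic-data
# compilations (NIST / IUPAC representative isotopic composition).  The
# first entry whose abundance is the maximum for the element is treated as
# the principal (monoisotopic) species.
#
# Users may supply their own table with the same layout to override these
# numbers (e.g. enriched solvents, different terrestrial source).
H:
  - {mass_number: 1, mass: 1.0078250319, abundance: 0.999885}
  - {mass_number: 2, mass: 2.0141017780, abundance: 0.000115}
C:
  - {mass_number: 12, mass: 12.0000000000, abundance: 0.9893}
  - {mass_number: 13, mass: 13.0033548378, abundance: 0.0107}
N:
  - {mass_number: 14, mass: 14.0030740052, abundance: 0.99636}
  - {mass_number: 15, mass: 15.0001088984, abundance: 0.00364}
O:
  - {mass_number: 16, mass: 15.9949146221, abundance: 0.99757}
  - {mass_number: 17, mass: 16.9991315000, abundance: 0.00038}
  - {mass_number: 18, mass: 17.9991604000, abundance: 0.00205}
P:
  - {mass_number: 31, mass: 30.9737615100, abundance: 1.0}
S:
  - {mass_number: 32, mass: 31.9720706900, abundance: 0.9499}
  - {mass_number: 33, mass: 32.9714585000, abundance: 0.0075}
  - {mass_number: 34, mass: 33.9678668300, abundance: 0.0425}
  - {mass_number: 36, mass: 35.9670808800, abundance: 0.0001}
Se:
  - {mass_number: 74, mass: 73.9224766000, abundance: 0.0089}
  - {mass_number: 76, mass: 75.9192141000, abundance: 0.0937}
  - {mass_number: 77, mass: 76.9199146000, abundance: 0.0763}
  - {mass_number: 78, mass: 77.9173095000, abundance: 0.2377}
  - {mass_number: 80, mass: 79.9165218000, abundance: 0.4961}
  - {mass_number: 82, mass: 81.9167000000, abundance: 0.0873}
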
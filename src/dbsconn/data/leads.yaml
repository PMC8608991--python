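# Registry of quadripolar DBS lead geometries.
# Lengths in mm; tip_to_first_contact_mm is the distance from the lead tip
# to the centre of the most distal contact (C0).
version: 1
leads:
  medtronic3389:
    n_contacts: 4
    contact_length_mm: 1.5
    intercontact_gap_mm: 0.5
    tip_to_first_contact_mm: 0.75
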
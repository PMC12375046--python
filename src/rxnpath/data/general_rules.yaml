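# Bundled general organic chemical-logic library.
#
# Patterns are written against single-bond skeleton graphs (bond orders are not
# perceived mid-exploration), so they use generic "~" bonds and connectivity
# primitives rather than bond-order primitives.  Each rule proposes exactly one
# bond form/break event between its two mapped atoms; concerted multi-bond
# events emerge from several rules firing at the same exploration depth.
version: "1.0"
rules:
  - rule_id: cycloaddition_cc
    name: carbon-carbon addition (cycloaddition terminus)
    smarts: "[#6;X1,X2,X3:1].[#6;X1,X2,X3:2]"
    action: form
    mapped_pair: [1, 2]
    provenance: general
    notes: >
      Unsaturated-carbon pairing; one terminus of a cycloaddition or radical
      C-C coupling. Fires across fragments or at >=3 bonds separation.
  - rule_id: nucleophilic_addition_co
    name: heteroatom-to-carbon nucleophilic addition
    smarts: "[#7,#8;!X4:1].[#6;X1,X2,X3:2]"
    action: form
    mapped_pair: [1, 2]
    provenance: general
    notes: N/O lone pair attacking an unsaturated carbon.
  - rule_id: proton_transfer
    name: proton transfer to heteroatom
    smarts: "[#1;X1:1].[#7,#8:2]"
    action: form
    mapped_pair: [1, 2]
    provenance: general
    notes: Bonded H migrating to an N/O acceptor.
  - rule_id: homolysis_cc
    name: carbon-carbon bond cleavage
    smarts: "[#6:1]~[#6:2]"
    action: break
    mapped_pair: [1, 2]
    provenance: general
    notes: Generic C-C scission; the energy filter decides feasibility.
  - rule_id: heterolysis_cx
    name: carbon-heteroatom bond cleavage
    smarts: "[#6:1]~[#7,#8,#9,#17,#35,#53:2]"
    action: break
    mapped_pair: [1, 2]
    provenance: general
    notes: C-X scission toward 1,2-migration and elimination channels.
  - rule_id: migration_h
    name: hydrogen 1,2-shift (C-H cleavage)
    smarts: "[#6:1]~[#1:2]"
    action: break
    mapped_pair: [1, 2]
    provenance: general
    notes: C-H cleavage; paired with proton_transfer this expresses H migration.
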
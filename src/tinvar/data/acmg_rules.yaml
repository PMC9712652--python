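# Default rule-based rubric for DEL/DUP classification (classes 1-5:
# benign, likely benign, uncertain significance, likely pathogenic,
# pathogenic). A simplified, declarative adaptation of dosage-based SV
# scoring: rules are evaluated top to bottom, first match wins; the
# fall-through class is 3 (uncertain significance), the conservative
# default for an unannotated call.
flags:
  - benign_region_overlap
  - constrained_gene_overlap
  - protein_coding_overlap
  - dosage_sensitive_loss
  - dosage_sensitive_loss_established
rules:
  - when: {benign_region_overlap: true}
    class: 2
  - when: {dosage_sensitive_loss_established: true}
    class: 5
  - when: {dosage_sensitive_loss: true}
    class: 4
  - when: {constrained_gene_overlap: true}
    class: 3
  - when: {protein_coding_overlap: true}
    class: 3
default_class: 3
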
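FWD_1	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG GCT CTC ATA CGA ACT CGT CC
FWD_2	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG TGC TCT CAT ACG AAC TCG TCC
FWD_3	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG ATG CTC TCA TAC GAA CTC GTC C
FWD_4	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG GAT GCT CTC ATA CGA ACT CGT CC
FWD_5	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG CGA TGC TCT CAT ACG AAC TCG TCC
FWD_6	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG TCG ATG CTC TCA TAC GAA CTC GTC C
FWD_7	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG ATC GAT GCT CTC ATA CGA ACT CGT CC
FWD_8	TCG TCG GCA GCG TCA GAT GTG TAT AAG AGA CAG GAT CGA TGC TCT CAT ACG AAC TCG TCC
RVS_1	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GGT CTC TGC TCG ACT AAC CAC
RVS_2	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GTG TCT CTG CTC GAC TAA CCA C
RVS_3	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GAT GTC TCT GCT CGA CTA ACC AC
RVS_4	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GGA TGT CTC TGC TCG ACT AAC CAC
RVS_5	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GCG ATG TCT CTG CTC GAC TAA CCA C
RVS_6	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GTC GAT GTC TCT GCT CGA CTA ACC AC
RVS_7	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GAT CGA TGT CTC TGC TCG ACT AAC CAC
RVS_8	GTC TCG TGG GCT CGG AGA TGT GTA TAA GAG ACA GGA TCG ATG TCT CTG CTC GAC TAA CCA C
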
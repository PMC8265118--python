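>TRX synthetic stand-in fusion-tag sequence
MSGLHNYVKNEIQIEPGRTKTNTTKYREKKDATMSTEKCNRGTIEQRPKPTGTDNAGKPQ
EDTQTFPWPWGSLGEFRKQWESEARHPMAKISNIHGDNTEVQQQSIKMS
>MBP synthetic stand-in fusion-tag sequence
MLHRTNEEYMDQKQKSKVSMETHEATETLLNDMTEELSSSMIDNSSIGYNTQKVRNKFHM
CMGVEQGQEMNKTQQHTKSKDFFGEVNTRNDQSHDKSETEKIEMGKGNAHRIKNRQVTSA
SPQLKLEENEIQGSGSQVNMENSQGSTRSGLTKRIVPLEKGMEDLEQMGNGNQLKKGKST
TDSDQDGLSGNFKANNPEQITDLAHHANDVPYEHTQQHTAFSMVKNKTPKNSGGVVNTTE
PIEQNQNNEIKGGTHGNTQNKCAHHIKNQLNFSQETMGANTSRKTNKCTYRIKHEHDSEV
NQEGDGEMNNRSQWHPGGLLKTPYALGMGDTGDQNMGNHGEAHADKKKTMENVHTLKKVY
NEYGYN
>SUMO synthetic stand-in fusion-tag sequence
MGDRYTNGRENKQDSIVSQNKLNPGGSGMDAGQAYQGDGYKYNNQKTDTSTESGGLGPKN
YNYRRTEFYSVQFTTPPMREDRRMTSHDIQCMYLLDNF
>GST synthetic stand-in fusion-tag sequence
MLNKSGSNPQLKAESQHENNRMSAMKDHKEHWGPQEKTALAPSTVLDNQSRWQGPEKGHF
DYVMTTPDTIEKKEEETTASSVESEEVQDKTHMFSPDPTLIQEVIQGKGRKGTNGEMCPL
LINNQHQDKINDMQDTTNQPAFDTRESPIPSNVNEIEINQEKQDEHDNMKYEYTWYNVNQ
QVQTFPYNTKPGDMGDNWHSYEQYDKNSSQD
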
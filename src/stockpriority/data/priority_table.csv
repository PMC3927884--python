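state,river,ale_demographic,ale_stock,ale_priority,bb_demographic,bb_stock,bb_priority
ME,Dennys,N,NNE,Medium,N,NNE,Medium
ME,East Machias,N,NNE,Medium,N,NNE,Medium
ME,Narraguagus,N,NNE,Medium,N,NNE,Medium
ME,Union,Y,NNE,Low,N,NNE,Medium
ME,Orland,N,NNE,Medium,N,NNE,Medium
ME,Penobscot,N,NNE,Medium,N,NNE,Medium
ME,Soudabscook,N,NNE,Medium,N,NNE,Medium
ME,St George,N,NNE,Medium,N,NNE,Medium
ME,Damariscotta,Y,NNE,Medium,N,NNE,Medium
ME,Sheepscot,N,NNE,Medium,N,NNE,Medium
ME,Kennebec,N,NNE,Medium,N,NNE,Medium
ME,Androscoggin,Y,NNE,Medium,N,NNE,Medium
ME,Presumpscot,N,NNE,Medium,N,NNE,Medium
ME,Saco,N,NNE,Medium,N,NNE,Medium
NH,Cocheco,Y,NNE,Medium,Y,NNE,Medium
NH,Oyster,N,NNE,Medium,Y,NNE,High
NH,Exeter,Y,NNE,Medium,N,NNE,Medium
NH,Lamprey,Y,NNE,Low,N,NNE,Medium
NH,Winnicut,Y,NNE,Low,Y,NNE,Medium
MA,Merrimac,N,SNE,High,N,SNE,High
MA,Parker,Y,SNE,Medium,N,SNE,High
MA,Mystic,N,SNE,High,N,SNE,High
MA,Charles,N,SNE,High,N,SNE,High
MA,Stony Brook,Y,SNE,High,N,SNE,High
MA,Town Brook,N,SNE,High,N,SNE,High
MA,Monument,Y,SNE,High,Y,SNE,High
MA,Mattipoisett,Y,SNE,High,N,SNE,High
MA,Nemasket,Y,SNE,High,N,SNE,High
RI,Nonquit,Y,SNE,High,N,SNE,High
RI,Gilbert Stuart,Y,SNE,Low,N,SNE,High
CT,Connecticut,N,SNE,High,Y,MAT,Medium
CT,Quinnipiac,N,SNE,High,N,MAT,High
CT,Housatonic,N,SNE,High,N,MAT,High
NY,Hudson,Y,SNE,High,Y,MAT,High
NJ,Raritan,N,MAT,Medium,N,MAT,High
NJ/DE/PA,Delaware,N,MAT,Medium,N,MAT,High
MD,Nanticoke,Y,MAT,Medium,Y,MAT,High
MD,Susquehanna,N,MAT,Medium,N,MAT,High
MD/VA,Potomac,N,MAT,Medium,N,MAT,High
VA,Rappahannock,Y,MAT,Low,N,MAT,High
VA,York,Y,MAT,Low,N,MAT,High
VA,James,Y,MAT,Medium,N,MAT,High
NC,Chowan,Y,MAT,High,Y,MAT,High
NC,Roanoke,N,MAT,High,N,MAT,High
NC,Alligator,N,MAT,High,N,MAT,High
NC,Tar-Pamlico,,,,N,MAT,High
NC,Neuse,,,,N,MAT,High
NC,Cape Fear,,,,N,SAT,Medium
SC,Pee Dee,,,,N,SAT,Medium
SC,Santee,,,,Y,SAT,Medium
SC,Cooper,,,,Y,SAT,Medium
SC,Edisto,,,,N,SAT,Medium
SC/GA,Savannah,,,,N,SAT,Medium
GA,Altamaha,,,,N,SAT,Medium
FL,St Johns,,,,Y,SAT,High
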
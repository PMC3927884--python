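species,river,code,state,year,n
alewife,East Machias,EMA,ME,2010,58
alewife,St George,STG,ME,2010,69
alewife,Lamprey,LAM,NH,2010,47
alewife,Mystic,MYS,MA,2010,68
alewife,Town Brook,TOW,MA,2011,46
alewife,Monument,MON,MA,2011,49
alewife,Gilbert Stuart,GIL,RI,2011,44
alewife,Thames,THA,CT,2009,36
alewife,Bride Brook,BRI,CT,2009,34
alewife,Connecticut,CON,CT,2009,7
alewife,Connecticut,CON,CT,2011,26
alewife,Quinnipiac,QUI,CT,2009,25
alewife,Housatonic,HOU,CT,2008,13
alewife,Housatonic,HOU,CT,2009,25
alewife,Mianus,MIA,CT,2009,25
alewife,Hudson,HUD,NY,2009,13
alewife,Hudson,HUD,NY,2012,48
alewife,Delaware,DEL,NJ,2011,42
alewife,Nanticoke,NAN,MD,2011,58
alewife,Rappahannock,RAP,VA,2011,62
alewife,Chowan,CHO,NC,2011,54
alewife,Roanoke,ROA,NC,2011,49
alewife,Alligator,ALL,NC,2011,49
blueback,East Machias,EMA,ME,2010,57
blueback,St George,STG,ME,2010,42
blueback,Exeter,EXE,NH,2010,41
blueback,Mystic,MYS,MA,2010,66
blueback,Monument,MON,MA,2011,50
blueback,Gilbert Stuart,GIL,RI,2011,38
blueback,Connecticut,CON,CT,2008,34
blueback,Connecticut,CON,CT,2009,62
blueback,Connecticut,CON,CT,2011,46
blueback,Hudson,HUD,NY,2009,77
blueback,Delaware,DEL,NJ,2011,48
blueback,Nanticoke,NAN,MD,2011,24
blueback,Rappahannock,RAP,VA,2011,58
blueback,James,JAM,VA,2011,97
blueback,Chowan,CHO,NC,2010,12
blueback,Chowan,CHO,NC,2011,58
blueback,Roanoke,ROA,NC,2011,50
blueback,Neuse,NEU,NC,2011,65
blueback,Cape Fear,CFE,NC,2011,57
blueback,Santee,SAN,SC,2011,61
blueback,Savannah,SAV,GA,2011,51
blueback,Altamaha,ALT,GA,2011,52
blueback,St Johns,STJ,FL,2011,37
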
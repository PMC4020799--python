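bird,colony,deployment_date,departure_date,end_date,duration_days,max_distance_colony_km,min_distance_covered_km,mean_daily_km,sd_daily_km,max_daily_km
WaRu,FI,11.12.2007,13.12.2007,29.01.2008,49,779,2438,51,28,134
Gus,FI,11.12.2007,14.12.2007,31.01.2008,51,668,1837,38,22,82
Susi,FI,11.12.2007,13.12.2007,03.02.2008,54,1032,2781,52,24,137
RuWa,FI,11.12.2007,13.12.2007,15.02.2008,66,960,3212,49,23,109
Iona,FI,11.12.2007,18.12.2007,22.02.2008,73,696,2848,43,27,94
Caldera,FI,11.12.2007,13.12.2007,07.03.2008,87,841,3096,36,22,98
Hansueli,FI,11.12.2007,18.12.2007,21.04.2008,132,1977,5286,42,22,106
Leo,FI,11.12.2007,14.12.2007,29.04.2008,140,4015,6320,46,24,106
Jacki,FI,11.12.2007,13.12.2007,12.05.2008,153,3132,6794,45,26,127
Youngster,FI,11.12.2007,13.12.2007,28.08.2008,261,4783,11712,45,23,107
Ueli,SG,13.12.2007,15.12.2007,28.02.2008,77,847,2374,31,23,105
Ursula,SG,13.12.2007,16.12.2007,29.02.2008,78,661,3192,43,23,81
Saanenland,SG,13.12.2007,17.12.2007,13.03.2008,91,834,3602,41,23,113
Tankini,SG,13.12.2007,16.12.2007,04.04.2008,113,1130,5456,50,23,98
Dixi,SG,13.12.2007,15.12.2007,22.05.2008,161,2603,7386,46,28,124
Traudel,SG,13.12.2007,16.12.2007,03.06.2008,173,2648,9114,54,27,135
Wicky,SG,13.12.2007,20.12.2007,06.06.2008,176,2150,7570,45,22,105
King Georg,SG,13.12.2007,17.12.2007,06.06.2008,176,3445,6684,39,24,174
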
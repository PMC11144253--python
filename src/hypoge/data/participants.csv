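id,gender,age,bmi,hba1c,treatment,t1dm_years
HUPA001,F,56.3,22.8,8.2,CSII,15.5
HUPA002,M,48.6,23.8,7.1,CSII,36.5
HUPA003,F,43.4,18.7,7.3,CSII,12.5
HUPA004,M,41.2,27.2,7.8,CSII,8.5
HUPA005,F,20.9,22.6,6.9,CSII,39.5
HUPA006,M,22.1,24.6,7.8,CSII,13.5
HUPA007,M,37.6,30.6,6.6,CSII,10.1
HUPA010,F,41.9,19.0,6.0,CSII,15.2
HUPA011,F,35.0,23.9,7.8,CSII,27.3
HUPA014,F,50.0,25.4,8.5,MDI,12.9
HUPA015,F,43.1,22.3,6.4,MDI,11.2
HUPA016,F,29.9,26.3,6.5,CSII,20.1
HUPA017,F,26.3,22.2,8.2,MDI,24.2
HUPA018,F,32.3,20.5,7.2,CSII,25.6
HUPA019,M,18.0,24.7,7.1,MDI,7.6
HUPA020,M,45.7,25.4,9.7,MDI,13.5
HUPA021,F,48.6,24.4,7.5,MDI,2.2
HUPA022,M,59.6,24.2,6.7,CSII,14.6
HUPA023,M,22.9,18.5,7.7,MDI,0.8
HUPA024,M,47.9,26.6,8.3,MDI,35.9
HUPA025,M,38.1,29.6,7.0,CSII,20.3
HUPA026,F,61.8,29.4,7.2,MDI,21.5
HUPA027,M,26.4,22.2,7.0,MDI,23.7
HUPA028,F,21.2,21.9,6.1,MDI,2.0
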
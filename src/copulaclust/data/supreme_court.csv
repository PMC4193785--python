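actor,President election,Federalism,Clean Water,Title VI Disabilities,Tobacco Ads,Labour rights,Property Rights,Citizenship,Free Speech,Seat Belts,United Foods,NYT Copyright,Cannabis for Health,Clean Air Act,PGA vs. Handicapped,Illegal Search 3,Illegal Search 1,Illegal Search 2,Stay of Execution,Privacy,Immigration Jurisdiction,Detaining Criminal Aliens,Legal Aid for the Poor,Voting Rights,Deporting Criminal Aliens,Campaign Finance
Breyer,-1,-1,-1,-1,-1,-1,-1,-1,1,-1,-1,-1,0,1,1,1,1,1,1,1,1,1,1,1,1,1
Ginsburg,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
Stevens,-1,-1,-1,-1,-1,-1,-1,1,-1,-1,1,-1,1,1,1,-1,1,1,1,1,1,1,1,1,1,1
Souter,-1,-1,-1,-1,-1,-1,-1,-1,-1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
O'Connor,1,1,1,1,1,1,1,-1,1,-1,-1,1,1,1,1,-1,1,1,1,1,-1,-1,-1,1,1,1
Kennedy,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,-1,1,1,1,1,1,1,1,-1,-1,-1
Rehnquist,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1
Scalia,1,1,1,1,1,1,1,1,1,1,1,1,1,1,-1,1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1
Thomas,1,1,1,1,1,1,1,1,1,1,1,1,1,1,-1,1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1
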
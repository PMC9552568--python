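JAMES
MARY
ROBERT
PATRICIA
JOHN
JENNIFER
MICHAEL
LINDA
DAVID
ELIZABETH
WILLIAM
BARBARA
RICHARD
SUSAN
JOSEPH
JESSICA
THOMAS
SARAH
CHARLES
KAREN
CHRISTOPHER
LISA
DANIEL
NANCY
MATTHEW
BETTY
ANTHONY
MARGARET
MARK
SANDRA
DONALD
ASHLEY
STEVEN
KIMBERLY
PAUL
EMILY
ANDREW
DONNA
JOSHUA
MICHELLE
KENNETH
DOROTHY
KEVIN
CAROL
BRIAN
AMANDA
GEORGE
MELISSA
EDWARD
DEBORAH
RONALD
STEPHANIE
TIMOTHY
REBECCA
JASON
SHARON
JEFFREY
LAURA
RYAN
CYNTHIA
JACOB
KATHLEEN
GARY
AMY
NICHOLAS
ANGELA
ERIC
SHIRLEY
JONATHAN
ANNA
STEPHEN
BRENDA
LARRY
PAMELA
JUSTIN
NICOLE
SCOTT
EMMA
BRANDON
SAMANTHA
BENJAMIN
KATHERINE
SAMUEL
CHRISTINE
GREGORY
DEBRA
FRANK
RACHEL
ALEXANDER
CATHERINE
RAYMOND
CAROLYN
PATRICK
JANET
JACK
RUTH
DENNIS
MARIA
JERRY
HEATHER
TYLER
DIANE
AARON
VIRGINIA
JOSE
JULIE
ADAM
JOYCE
HENRY
VICTORIA
NATHAN
OLIVIA
DOUGLAS
KELLY
ZACHARY
CHRISTINA
PETER
LAUREN
KYLE
JOAN
WALTER
EVELYN
ETHAN
JUDITH
JEREMY
MEGAN
HAROLD
CHERYL
KEITH
ANDREA
CHRISTIAN
HANNAH
ROGER
MARTHA
NOAH
JACQUELINE
GERALD
FRANCES
CARL
GLORIA
TERRY
ANN
SEAN
TERESA
AUSTIN
KATHRYN
ARTHUR
SARA
LAWRENCE
JANICE
JESSE
JEAN
DYLAN
ALICE
BRYAN
MADISON
JOE
DORIS
JORDAN
ABIGAIL
BILLY
JULIA
BRUCE
JUDY
ALBERT
GRACE
WILLIE
DENISE
GABRIEL
AMBER
LOGAN
MARILYN
ALAN
BEVERLY
JUAN
DANIELLE
WAYNE
THERESA
ROY
SOPHIA
RALPH
MARIE
RANDY
DIANA
EUGENE
BRITTANY
VINCENT
NATALIE
RUSSELL
ISABELLA
ELIJAH
CHARLOTTE
LOUIS
ROSE
BOBBY
ALEXIS
PHILIP
KAYLA
JOHNNY
LORI
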